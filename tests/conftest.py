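import numpy as np
import pytest

from bcpflow.germline import make_germline_db


@pytest.fixture(scope="session")
def db():
    return make_germline_db()


@pytest.fixture(scope="session")
def healthy_reference():
    """Reference model built from five simulated healthy controls (shared)."""
    from bcpflow.gating import gate_sample
    from bcpflow.reference_model import build_reference
    from bcpflow.synthetic_data import simulate_bm_sample

    controls = []
    for i in range(5):
        events, _ = simulate_bm_sample("healthy", 50_000, donor_id=f"ctrl{i}", seed=100 + i)
        controls.append(gate_sample(events))
    return build_reference(controls, k=2.0)


def frame_stop_oracle(db, seq, truth):
    """Independent translate-and-scan oracle for frame/stop classification.

    Translates from V codon 1 with Biopython; in-frame iff the J-Trp anchor
    offset is a multiple of three; stop iff '*' appears in the translation
    through the anchor codon.
    """
    from Bio.Seq import Seq

    from bcpflow.synthetic_data import truth_anchor_positions

    _, trp = truth_anchor_positions(db, truth)
    in_frame = trp % 3 == 0
    n_codons = trp // 3 + 1
    aa = str(Seq(seq[: 3 * n_codons]).translate())
    stop = "*" in aa
    if in_frame and not stop:
        return "in_frame"
    if not in_frame:
        return "unproductive_out_of_frame"
    return "unproductive_stop"
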