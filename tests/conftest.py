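import numpy as np
import pytest

from carotidwave.cycle_processing import detect_systole_feet, ensemble_average
from carotidwave.hemodynamics import flow_waveform, pwv_qa_loop
from carotidwave.synthwave import HemoTruth, synthesize_waveforms


@pytest.fixture
def chain_pwv():
    """Waveform-level analysis chain: synthesize → segment → average → QA fit.

    Returns a callable mapping a HemoTruth to (pwv_estimate, mean_cycle_dict,
    diagnostics).
    """

    def _run(truth: HemoTruth, n_cycles: int = 8, fs: float = 2000.0,
             rr_jitter: float = 0.0):
        wf = synthesize_waveforms(truth, n_cycles=n_cycles, fs=fs,
                                  rr_jitter=rr_jitter)
        feet = detect_systole_feet(wf.t, wf.V)
        ens = ensemble_average(wf.t, {"A": wf.A, "V": wf.V}, feet)
        A, V = ens.mean_cycle["A"], ens.mean_cycle["V"]
        Q, _ = flow_waveform(A, V)
        pwv, diag = pwv_qa_loop(Q, A)
        return pwv, {"A": A, "V": V, "Q": Q, "ens": ens}, diag

    return _run
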