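"""Shared settings for the numbered analysis drivers.

Every driver regenerates the same synthetic trial deterministically (seed
2026, 527 participants per arm — the trial's size) so each can be run on its
own; outputs accumulate under ``results/``.
"""

from pathlib import Path

from oviva_cea import SynthConfig, generate_trial

SEED = 2026
N_PER_ARM = 527
RESULTS = Path(__file__).resolve().parent.parent / "results"


def trial():
    RESULTS.mkdir(exist_ok=True)
    return generate_trial(SynthConfig.oviva(n_per_arm=N_PER_ARM, seed=SEED))
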