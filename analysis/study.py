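"""Shared study definition for the numbered analysis scripts.

One master seed and one synthetic study configuration (the package
defaults: four crops led by wheat, 52-compound assessment group, 1724-adult
dietary survey) so every script regenerates its inputs deterministically
instead of passing bulky intermediates around.  Small summary tables go to
``results/``; bulky intermediates, when a script chooses to dump them, go to
``scratch/`` which is not part of the deliverable.
"""

from pathlib import Path

from aggexpo.config import SyntheticConfig

STUDY_SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

I_PER_CROP = 2000
N_UNIT_DOSE = 17_500


def study_config() -> SyntheticConfig:
    """The study conditions: package defaults with the master seed."""
    import dataclasses

    return dataclasses.replace(SyntheticConfig(), seed=STUDY_SEED)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
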