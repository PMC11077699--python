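"""Shared study conditions for the analysis scripts.

One 59-gene family on 12 chromosomes under the default study-condition
mix, with three divergent duplicate pairs. Regenerated deterministically
by every script (generation takes ~1 s), so no script depends on another
having run first. Bulky per-run data lands in scratch/, small summary
tables in results/.
"""

from pathlib import Path

from pcfam.synthetic import FamilySimConfig, generate_family

SEED = 17
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_family():
    return generate_family(FamilySimConfig(seed=SEED))


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def scratch_dir() -> Path:
    SCRATCH.mkdir(exist_ok=True)
    return SCRATCH
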