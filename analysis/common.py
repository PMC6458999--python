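"""Shared helpers for the analysis drivers: one cached pipeline run per seed."""

import pickle
from pathlib import Path

from pasfactory.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_run(seed: int = 1):
    """Full default-condition pipeline run, cached as a pickle under scratch/."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"run_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    res = run_pipeline(RunConfig(seed=seed))
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res
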