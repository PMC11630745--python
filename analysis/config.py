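"""Shared configuration for the numbered analysis drivers.

All drivers operate on the same simulated cohort (the study's group sizes)
and write artifacts under results/.  Run them in order; each stage reads only
the serialized outputs of the previous ones.
"""

import argparse
from pathlib import Path

from speechlex.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent


def default_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        cohort_dir=str(ROOT / "results" / "cohort"),
        test_cohort_dir=str(ROOT / "results" / "test_cohort"),
        out_dir=str(ROOT / "results" / "run"),
        seed=seed,
        simulate_n_words=500,
    )


def parse_args(description: str) -> RunConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = default_config(seed=args.seed)
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    return cfg
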