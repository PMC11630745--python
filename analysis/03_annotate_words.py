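"""Annotate every content token with its eight psycholinguistic properties
(length, log frequency, semantic diversity, semantic neighbourhood density,
concreteness, age of acquisition, OLD20, PLD20) from the norms lexicon,
with singular-form fallback for plurals.  Reports annotation coverage."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_annotate


def main():
    cfg = parse_args(__doc__)
    stage_annotate(cfg)
    cov = pd.read_csv(Path(cfg.out_dir) / "annotation_coverage.csv")
    tot = cov[["total_tokens", "function_tokens", "annotated_tokens",
               "dropped_tokens", "fallback_tokens"]].sum()
    print("token coverage across the cohort:")
    print(f"  total            {tot.total_tokens}")
    print(f"  function words   {tot.function_tokens}")
    print(f"  annotated        {tot.annotated_tokens}"
          f" ({100 * tot.annotated_tokens / (tot.total_tokens - tot.function_tokens):.1f}% of content)")
    print(f"  dropped (no norms entry) {tot.dropped_tokens}")
    print(f"  via singular fallback    {tot.fallback_tokens}")


if __name__ == "__main__":
    main()
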