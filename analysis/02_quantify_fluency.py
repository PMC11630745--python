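"""Compute the 13 speech-fluency measures per transcript (token/type counts
for words, bigrams and trigrams; TTRs; time and words per minute; the
function/content proportion; the combination ratio).  Expect reduced output
and rate in the motor groups (nfvPPA, PSP, CBS)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_quantify


def main():
    cfg = parse_args(__doc__)
    stage_quantify(cfg)
    wide = pd.read_csv(Path(cfg.out_dir) / "fluency_wide.csv")
    summary = wide.groupby("group")[
        ["word_tokens", "words_per_minute", "ttr_word", "combination_ratio"]
    ].mean().round(2)
    print("group means over both pictures:")
    print(summary.to_string())
    print(f"\nwide table: {cfg.out_dir}/fluency_wide.csv "
          f"({len(wide)} participant x picture rows)")


if __name__ == "__main__":
    main()
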