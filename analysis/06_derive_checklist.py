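"""Derive the 15-word checklists: indicator-code all unique content words
(with inflection/variant equivalence), screen by L1-penalized logistic
regression over all 15 pairwise group contrasts, pool the survivors, re-fit,
rank by (appearances, max |beta|, production-proportion difference), and
keep the top 15 per picture.  Contrasts the penalty empties (e.g. nfvPPA vs
PSP) motivate the hierarchical classifier used next."""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_derive_checklist


def main():
    cfg = parse_args(__doc__)
    stage_derive_checklist(cfg)
    out = Path(cfg.out_dir)
    for pic in ("cookie_theft", "beach_scene"):
        sel = json.loads((out / f"selection_{pic}.json").read_text())
        ranked = pd.read_csv(out / f"ranked_words_{pic}.csv")
        print(f"{pic}: {sel['n_candidate_words']} candidate words -> "
              f"{len(sel['pooled_words'])} pooled -> top {min(15, len(ranked))}")
        print("  checklist:", ", ".join(ranked.head(15)["word"]))
        if sel["zero_word_contrasts"]:
            zc = ", ".join(f"{a} vs {b}" for a, b in sel["zero_word_contrasts"])
            print(f"  contrasts with zero selected words: {zc}")


if __name__ == "__main__":
    main()
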