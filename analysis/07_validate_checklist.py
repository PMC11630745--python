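"""Validate the checklists hierarchically: patients vs controls, then motor
(nfvPPA/PSP/CBS) vs lexico-semantic (svPPA/lvPPA), then pairs within each
cluster (PSP+CBS merged), by stratified 4-fold cross-validation and on the
held-out cohort; repeated with ACE-R/MLSE sub-scores supplementing the word
indicators for the pairs that words alone cannot separate."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_validate


def main():
    cfg = parse_args(__doc__)
    stage_validate(cfg)
    out = Path(cfg.out_dir)
    v = json.loads((out / "validation.json").read_text())
    for pic, schemes in v.items():
        print(pic)
        for scheme, reports in schemes.items():
            line = ", ".join(
                f"{name}: {100 * rep['accuracy']:.0f}%"
                f" (sens {100 * rep['sensitivity']:.0f}/spec {100 * rep['specificity']:.0f})"
                for name, rep in reports.items()
            )
            print(f"  {scheme}: {line}")
    print(f"\nfull report: {out}/validation.json")


if __name__ == "__main__":
    main()
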