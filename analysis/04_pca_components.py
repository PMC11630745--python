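"""Dual varimax-rotated PCA.  Fluency measures -> 'speech quanta', 'lexical
richness', 'speech complexity'; pooled-corpus word properties -> 'length',
'semantic richness', 'acquisition age'.  Components chosen by the scree
elbow (three expected), adequacy checked by KMO, group effects by ANOVA."""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_pca


def main():
    cfg = parse_args(__doc__)
    stage_pca(cfg)
    out = Path(cfg.out_dir)
    tests = json.loads((out / "pca_tests.json").read_text())
    print("components retained:", tests["k"],
          " KMO:", {k: (round(v, 2) if v is not None else None) for k, v in tests["kmo"].items()})
    print("variance explained:",
          {k: f"{100 * v:.1f}%" for k, v in tests["explained_variance"].items()})
    flu = json.loads((out / "fluency_pca.json").read_text())
    L = pd.DataFrame(flu["loadings"], index=flu["feature_names"],
                     columns=[f"PC{i+1}" for i in range(flu["k"])])
    print("\nfluency PCA loadings (varimax):")
    print(L.round(2).to_string())
    print("\none-way group ANOVA on fluency PC scores:")
    for comp, res in tests["fluency_one_way"].items():
        print(f"  {comp}: F={res['F']:.2f}, p={res['p']:.2g}")
    print("\ntwo-way group x picture ANOVA on averaged word PC scores:")
    for comp, res in tests["word_two_way"].items():
        print(f"  {comp}: group F={res['F_group']:.2f} (p={res['p_group']:.2g}), "
              f"task F={res['F_task']:.2f}, interaction F={res['F_interaction']:.2f}")


if __name__ == "__main__":
    main()
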