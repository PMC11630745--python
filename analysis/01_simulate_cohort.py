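"""Simulate the study cohort: 24 controls, 9 svPPA, 9 lvPPA, 9 nfvPPA,
10 PSP, 13 CBS, each describing the 'cookie theft' and 'beach scene'
pictures, plus a disjoint same-language test cohort for out-of-sample
validation.  Writes transcripts, manifest, norms lexicon and ground truth."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import parse_args

from speechlex.pipeline import stage_simulate
from speechlex.transcripts import parse_transcript, read_manifest, read_transcript


def main():
    cfg = parse_args(__doc__)
    stage_simulate(cfg)
    manifest = read_manifest(Path(cfg.cohort_dir) / "manifest.csv")
    print(f"training cohort: {len(manifest)} transcripts -> {cfg.cohort_dir}")
    by_group = {}
    for row in manifest:
        if row.picture.value != "cookie_theft":
            continue
        t = parse_transcript(read_transcript(Path(cfg.cohort_dir) / row.path))
        by_group.setdefault(row.group.value, []).append(t.n_tokens)
    print("mean retained tokens per group (cookie theft):")
    for g, counts in by_group.items():
        print(f"  {g:8s} n={len(counts):2d}  {sum(counts) / len(counts):6.1f}")
    test = read_manifest(Path(cfg.test_cohort_dir) / "manifest.csv")
    print(f"test cohort: {len(test)} transcripts -> {cfg.test_cohort_dir}")


if __name__ == "__main__":
    main()
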