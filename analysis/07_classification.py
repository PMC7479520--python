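"""Patient-group classification from CN-specific functional subset
frequencies: L1 logistic regression under repeated hold-out (10 training
patients per group), coefficient-z-score feature importance, and the CN
functional-state alteration score per subset.

Reads results/cells_with_cn.csv; writes classification_auc.csv,
importance.csv, alteration.csv.
"""

import pandas as pd

from _shared import FUNCTIONAL_SUBSETS, load_labeled, parser
from cncoord import Subset, compute_frequencies
from cncoord.classification import (alteration_score, classify_groups,
                                    feature_importance)


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel] + FUNCTIONAL_SUBSETS
    tables = compute_frequencies(ds, subsets)
    groups = ds.group_indicator()

    names = [s.name for s in FUNCTIONAL_SUBSETS]
    cols = [c for c in tables.cn_specific.columns if c[1] in names]
    feats = tables.cn_specific[cols].copy()
    feats.columns = [f"{s}@CN{c}" for c, s in cols]
    n_reps = 100 if args.quick else 1000
    rep = classify_groups(feats, groups, n_reps=n_reps, seed=args.seed)
    pd.DataFrame({"auc": rep.aucs}).to_csv(
        args.results / "classification_auc.csv", index=False)
    imp = feature_importance(rep)
    imp.to_csv(args.results / "importance.csv", index_label="feature")

    rho = 50 if args.quick else 200
    rows = []
    for name in names:
        alt = alteration_score(tables, name, groups, rho_reps=rho,
                               outer_reps=10, seed=args.seed)
        rows.append({"subset": name, "median_score": alt.median,
                     **{f"rep{i}": s for i, s in enumerate(alt.scores)}})
    pd.DataFrame(rows).to_csv(args.results / "alteration.csv", index=False)
    best = max(rows, key=lambda r: r["median_score"])
    print(f"mean hold-out AUC = {rep.aucs.mean():.3f} over {n_reps} reps; "
          f"top importance: {imp['importance'].idxmax()}; "
          f"highest alteration score: {best['subset']} "
          f"({best['median_score']:.1f})")


if __name__ == "__main__":
    main()
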