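"""Per-patient overall and CN-specific subset frequencies, marker-positivity
proportions per CN, group t-tests on CN frequencies, and PCA of cell-type
abundances.

Reads results/cells_with_cn.csv; writes cn_specific.csv, overall.csv,
marker_proportions.csv, cn_group_tests.csv, pca_scores.csv.
"""

import pandas as pd

from _shared import FUNCTIONAL_SUBSETS, load_labeled, parser
from cncoord import Subset, compute_frequencies
from cncoord.frequencies import (compare_group_frequencies, marker_proportions,
                                 pca_abundances)


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel] + FUNCTIONAL_SUBSETS
    tables = compute_frequencies(ds, subsets)
    cnspec = tables.cn_specific.copy()
    cnspec.columns = [f"{s}@CN{c}" for c, s in cnspec.columns]
    cnspec.to_csv(args.results / "cn_specific.csv")
    tables.overall.to_csv(args.results / "overall.csv")
    props = marker_proportions(ds, ds.markers, FUNCTIONAL_SUBSETS)
    props.to_csv(args.results / "marker_proportions.csv", index=False)

    groups = ds.clinical.set_index("patient_id")["group"]
    cn_freq = pd.read_csv(args.results / "cn_frequencies.csv",
                          index_col="patient_id")
    tests = compare_group_frequencies(cn_freq, groups)
    tests.to_csv(args.results / "cn_group_tests.csv")
    scores, loadings, evr = pca_abundances(tables.overall[ds.panel])
    scores.to_csv(args.results / "pca_scores.csv")
    sig = tests[tests["p"] < 0.05]
    print(f"{len(sig)} of {len(tests)} CN frequencies differ between groups "
          f"at p<0.05; PC1 explains {evr[0]:.1%} of abundance variance")


if __name__ == "__main__":
    main()
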