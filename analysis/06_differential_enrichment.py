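"""CN-specific differential enrichment of functional subsets between the
patient groups: OLS of log CN-specific frequency on group and log overall
frequency (pseudocount 1e-3), unadjusted p values as in the protocol.

Reads results/cells_with_cn.csv; writes enrichment.csv and
enrichment_flags.csv.
"""

from _shared import FUNCTIONAL_SUBSETS, load_labeled, parser
from cncoord import Subset, compute_frequencies
from cncoord.enrichment import differential_enrichment, enrichment_heatmap_table


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel] + FUNCTIONAL_SUBSETS
    tables = compute_frequencies(ds, subsets)
    res = differential_enrichment(tables, ds.group_indicator())
    res.to_csv(args.results / "enrichment.csv", index=False)
    coef, flags = enrichment_heatmap_table(res)
    flags.to_csv(args.results / "enrichment_flags.csv")
    hits = res[res["p"] < 0.05].sort_values("p")
    top = hits.iloc[0] if len(hits) else None
    msg = (f"strongest: {top['subset']} in CN{top['cn']} "
           f"(b1={top['beta1']:.2f}, p={top['p']:.2g})" if top is not None
           else "no hit below p=0.05")
    print(f"{len(hits)} of {len(res)} (CN, subset) pairs differentially "
          f"enriched at p<0.05; {msg}")


if __name__ == "__main__":
    main()
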