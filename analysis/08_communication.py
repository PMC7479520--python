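"""Inter-CN communication networks per patient group: first canonical
correlation of log CN-specific functional subset frequencies for every CN
pair, calibrated against a patient-permutation null; edges where the
observed correlation beats the 90th null percentile.

Reads results/cells_with_cn.csv; writes communication_<group>.csv.
"""

from _shared import FUNCTIONAL_SUBSETS, load_labeled, parser
from cncoord import Subset, compute_frequencies
from cncoord.communication import build_graph


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel] + FUNCTIONAL_SUBSETS
    names = [s.name for s in FUNCTIONAL_SUBSETS]
    n_perm = 500 if args.quick else 5000
    for grp in ds.groups:
        keep = ds.cells["patient_id"].isin(
            ds.clinical.loc[ds.clinical["group"] == grp, "patient_id"])
        sub = ds.with_cells(ds.cells[keep])
        tables = compute_frequencies(sub, subsets)
        g = build_graph(tables, names, n_perm=n_perm, seed=args.seed)
        g.edges.to_csv(args.results / f"communication_{grp}.csv", index=False)
        strong = (g.edges["tier"] == "strong").sum() if len(g.edges) else 0
        print(f"group {grp}: {len(g.edges)} communication edges "
              f"({strong} strong) among {len(g.nodes)} CNs")


if __name__ == "__main__":
    main()
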