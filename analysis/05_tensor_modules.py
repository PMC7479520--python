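"""Joint patients x cell types x CNs composition tensor per patient group,
rank-selection elbow scan, non-negative Tucker decomposition at ranks
(2,6,6), and the tissue-module bipartite graphs read off the core slices.

Reads results/cells_with_cn.csv; writes elbow_<group>.csv,
tucker_<group>.json, tissue_modules_<group>.csv.
"""

import pandas as pd

from _shared import parser, load_labeled
from cncoord import Subset, compute_frequencies
from cncoord.io import write_tucker
from cncoord.tensor import build_tensor, elbow_scan, tissue_modules, tucker_decompose


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel]
    for grp in ds.groups:
        keep = ds.cells["patient_id"].isin(
            ds.clinical.loc[ds.clinical["group"] == grp, "patient_id"])
        sub = ds.with_cells(ds.cells[keep])
        tables = compute_frequencies(sub, subsets)
        tens = build_tensor(tables, list(ds.panel))
        grid = [(2, r, r) for r in (2, 4, 6)] if args.quick else \
               [(p, r, r) for p in (1, 2) for r in (2, 4, 6, 8)]
        scan = elbow_scan(tens, grid, n_starts=2, seed=args.seed)
        scan.to_csv(args.results / f"elbow_{grp}.csv", index=False)
        ranks = tuple(min(r, d) for r, d in zip((2, 6, 6), tens.values.shape))
        fit = tucker_decompose(tens, ranks, n_starts=3, seed=args.seed)
        write_tucker(fit, args.results / f"tucker_{grp}.json")
        mods = pd.concat(tissue_modules(fit), ignore_index=True)
        mods.to_csv(args.results / f"tissue_modules_{grp}.csv", index=False)
        print(f"group {grp}: tensor {tens.values.shape}, ranks {ranks}, "
              f"relative loss {fit.rel_loss:.3f}, "
              f"{int(mods['active'].sum())} active module edges")


if __name__ == "__main__":
    main()
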