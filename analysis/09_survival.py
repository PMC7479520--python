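"""Survival analysis of CN-specific functional subset frequencies: Cox
proportional hazards on log(1e-3 + frequency) with likelihood-ratio p and
Schoenfeld PH diagnostic, plus Kaplan-Meier curves at the optimal covariate
split (log-rank p uncorrected for the scan).

Reads results/cells_with_cn.csv; writes survival.csv.
"""

import numpy as np
import pandas as pd

from _shared import FUNCTIONAL_SUBSETS, load_labeled, parser
from cncoord import Subset, compute_frequencies
from cncoord.survival import cox_cn_frequency, km_optimal_split, ph_diagnostic


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_labeled(args.results)
    subsets = [Subset(t) for t in ds.panel] + FUNCTIONAL_SUBSETS
    tables = compute_frequencies(ds, subsets)
    rows = []
    for s in FUNCTIONAL_SUBSETS:
        for cn in tables.occupancy.columns:
            col = (cn, s.name)
            if col not in tables.cn_specific.columns:
                continue
            freq = tables.cn_specific[col].fillna(0.0)
            try:
                fit = cox_cn_frequency(ds.clinical, freq,
                                       covariate_name=f"{s.name}@CN{cn}")
                ph = ph_diagnostic(fit)
                split = km_optimal_split(ds.clinical, np.log(1e-3 + freq))
                rows.append({"covariate": fit.covariate, "log_hr": fit.log_hr,
                             "se": fit.se, "p_lrt": fit.p_lrt, "ph_p": ph,
                             "split_logrank_p": split.logrank_p,
                             "n": fit.n, "n_events": fit.n_events})
            except ValueError:
                continue
    out = pd.DataFrame(rows).sort_values("p_lrt")
    out.to_csv(args.results / "survival.csv", index=False)
    top = out.iloc[0]
    print(f"{len(out)} Cox models fit; strongest prognostic covariate: "
          f"{top['covariate']} (log HR {top['log_hr']:.2f}, "
          f"LRT p = {top['p_lrt']:.3g}, PH p = {top['ph_p']:.2f})")


if __name__ == "__main__":
    main()
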