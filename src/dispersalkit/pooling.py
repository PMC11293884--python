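"""Population-level pooling of per-individual selection coefficients.

Individual iSSA coefficients are combined per site x state x term by a
fixed-effect inverse-variance weighted mean:

    beta_bar = sum(beta_i / se_i^2) / sum(1 / se_i^2)
    se_bar   = (sum 1 / se_i^2)^(-1/2)

with 95% normal-theory confidence intervals; a term is *significant* when
its CI excludes zero.  Cochran's Q and I^2 are reported for information
only and never alter the estimates.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .issa import IssaFit

log = logging.getLogger(__name__)

__all__ = ["pool", "compare_sites"]

Z95 = 1.959963984540054


def pool(fits: list[IssaFit], site: str = "site", state: str = "all",
         terms: list[str] | None = None) -> pd.DataFrame:
    """Inverse-variance pooled estimates per term across individuals.

    Non-converged fits (or terms with non-finite SE) are excluded with a
    log entry; a term left with fewer than one usable fit is reported as
    not estimable (NaN estimates, ``n_individuals`` 0).
    """
    usable = []
    for f in fits:
        if not f.converged:
            log.info("pool(%s/%s): excluding non-converged fit for %s", site, state, f.animal_id)
            continue
        usable.append(f)
    if terms is None:
        seen = {}
        for f in usable:
            for t in f.names:
                seen[t] = True
        terms = list(seen)
    rows = []
    for term in terms:
        betas, ws = [], []
        for f in usable:
            if term not in f.beta:
                continue
            se = f.se[term]
            if not np.isfinite(se) or se <= 0:
                log.info("pool(%s/%s): excluding %s for term %s (bad SE)",
                         site, state, f.animal_id, term)
                continue
            betas.append(f.beta[term])
            ws.append(1.0 / se**2)
        n = len(betas)
        if n == 0:
            rows.append({"site": site, "state": state, "term": term,
                         "beta_bar": np.nan, "se_bar": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_individuals": 0, "significant": False,
                         "Q": np.nan, "I2": np.nan})
            continue
        betas = np.asarray(betas)
        ws = np.asarray(ws)
        beta_bar = float(np.sum(ws * betas) / np.sum(ws))
        se_bar = float(1.0 / np.sqrt(np.sum(ws)))
        ci_low, ci_high = beta_bar - Z95 * se_bar, beta_bar + Z95 * se_bar
        q = float(np.sum(ws * (betas - beta_bar) ** 2))
        i2 = float(max(0.0, (q - (n - 1)) / q)) if n > 1 and q > 0 else 0.0
        rows.append({"site": site, "state": state, "term": term,
                     "beta_bar": beta_bar, "se_bar": se_bar,
                     "ci_low": ci_low, "ci_high": ci_high,
                     "n_individuals": n,
                     "significant": bool(ci_low > 0 or ci_high < 0),
                     "Q": q, "I2": i2})
    return pd.DataFrame(rows)


def compare_sites(pooled_a: pd.DataFrame, pooled_b: pd.DataFrame,
                  label_a: str | None = None, label_b: str | None = None) -> pd.DataFrame:
    """Side-by-side site comparison per term x state.

    ``both_sites_significant`` is set when both sites' CIs exclude zero on
    the same side (the forest-plot asterisk semantics); single-site
    significance flags are retained either way.
    """
    a = pooled_a.copy()
    b = pooled_b.copy()
    la = label_a or (str(a["site"].iloc[0]) if len(a) else "a")
    lb = label_b or (str(b["site"].iloc[0]) if len(b) else "b")
    keep = ["state", "term", "beta_bar", "se_bar", "ci_low", "ci_high",
            "n_individuals", "significant"]
    merged = a[keep].merge(b[keep], on=["state", "term"], suffixes=(f"_{la}", f"_{lb}"),
                           how="outer")
    sig_a = merged[f"significant_{la}"].fillna(False).astype(bool)
    sig_b = merged[f"significant_{lb}"].fillna(False).astype(bool)
    same_side = np.sign(merged[f"beta_bar_{la}"]) == np.sign(merged[f"beta_bar_{lb}"])
    merged["both_sites_significant"] = (sig_a & sig_b & same_side).fillna(False)
    return merged
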