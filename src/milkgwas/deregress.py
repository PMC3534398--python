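"""De-regression of EBVs free from parental averages.

Implements the parent-average-removal system of Garrick, Taylor &
Fernando (2009): the animal's EBV and its parent average are treated as
solutions of a two-equation mixed-model system whose information
contents are recovered from the two reliabilities, and the right-hand
side attributable to the animal's own data is divided by its own
information content.  The result is a pseudo-phenotype ("de-regressed
proof", DRP) carrying the animal's own information only, plus a record
weight usable for weighted residuals.

With no parent information and reliability -> 1, the DRP converges to
the EBV.  Records whose own reliability does not exceed the parent
average's carry no own information and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# reliabilities are clamped away from the poles to avoid division
# blow-ups; the PA reliability must also stay below 0.5 (its theoretical
# maximum from two parents) for the information equations to be defined
_R2_MIN = 0.01
_R2_MAX = 0.99
_PA_R2_MAX = 0.49


@dataclass(frozen=True)
class DeregressionResult:
    drp: float
    weight: float
    own_reliability: float      # reliability of the de-regressed record
    flagged: bool               # True when own information ~ absent


def deregress_one(
    ebv: float,
    reliability: float,
    pa_ebv: float | None,
    pa_reliability: float | None,
    h2: float,
    c: float = 0.5,
) -> DeregressionResult:
    """De-regress a single EBV.

    Parameters
    ----------
    ebv, reliability
        The animal's EBV and its reliability r².
    pa_ebv, pa_reliability
        Parent-average EBV and reliability; ``None`` for founders.
    h2
        Trait heritability used to form lambda = (1 - h²) / h².
    c
        Fraction of genetic variance not accounted for by markers, used
        only in the record weight.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    lam = (1.0 - h2) / h2
    r2 = float(np.clip(reliability, _R2_MIN, _R2_MAX))
    if pa_ebv is None or pa_reliability is None or np.isnan(pa_ebv):
        g_pa, r2_pa = 0.0, _R2_MIN
    else:
        g_pa = float(pa_ebv)
        r2_pa = float(np.clip(pa_reliability, _R2_MIN, _PA_R2_MAX))
    flagged = r2 <= r2_pa

    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2)
    zpa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(
        alpha**2 + 16.0 / delta
    )
    zi = delta * zpa + 2.0 * lam * (2.0 * delta - 1.0)
    if zi <= 0.0:
        return DeregressionResult(drp=np.nan, weight=0.0, own_reliability=0.0,
                                  flagged=True)
    # right-hand side attributable to the animal's own records
    y_i = -2.0 * lam * g_pa + (zi + 2.0 * lam) * float(ebv)
    drp = y_i / zi
    r2_drp = zi / (zi + lam)
    weight = (1.0 - h2) / ((c + (1.0 - r2_drp) / r2_drp) * h2)
    return DeregressionResult(drp=float(drp), weight=float(weight),
                              own_reliability=float(r2_drp), flagged=flagged)


def deregress_table(
    records: pd.DataFrame,
    h2: float | dict[str, float],
    c: float = 0.5,
) -> pd.DataFrame:
    """De-regress a proxy-record table (columns: animal, trait, ebv,
    reliability, pa_ebv, pa_reliability).

    Returns the table with ``drp``, ``weight``, ``drp_reliability`` and
    ``drp_flagged`` columns appended.  ``h2`` may be a single value or a
    per-trait mapping.
    """
    out = records.copy()
    drp = np.empty(len(out))
    weight = np.empty(len(out))
    rel = np.empty(len(out))
    flag = np.empty(len(out), dtype=bool)
    has_pa = {"pa_ebv", "pa_reliability"} <= set(out.columns)
    for k, row in enumerate(out.itertuples(index=False)):
        h2_t = h2[row.trait] if isinstance(h2, dict) else h2
        res = deregress_one(
            ebv=row.ebv,
            reliability=row.reliability,
            pa_ebv=row.pa_ebv if has_pa else None,
            pa_reliability=row.pa_reliability if has_pa else None,
            h2=h2_t,
            c=c,
        )
        drp[k], weight[k], rel[k], flag[k] = (
            res.drp, res.weight, res.own_reliability, res.flagged,
        )
    out["drp"] = drp
    out["weight"] = weight
    out["drp_reliability"] = rel
    out["drp_flagged"] = flag
    return out
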