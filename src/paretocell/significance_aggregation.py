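"""Cell-type significance aggregation with donor-majority voting and FDR control.

A cell type is called significant when at least 50% of its available donors
have some tissue stratum with a recorded p-value below alpha. For called
cell types, the probability of being a false positive is computed exactly:
each donor d with m_d recorded p-values (including excess p-values from the
dimension sweep) flags under the global null with probability
q_d = 1 - (1 - pi0 * alpha)^{m_d}, and the cell type's false-positive
probability is the Poisson-binomial tail P(#flagged donors >= ceil(D/2)),
evaluated by exact dynamic programming. pi0 — the estimated fraction of true
nulls among all recorded p-values — deflates the per-test null rate in the
style of the qvalue correction. Called cell types are finally accepted as
the largest prefix (ascending p_fp) whose mean false-positive probability
(the total FDR of the accepted set) stays below 0.10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CellTypeSignificance:
    cell_type: str
    donors_available: int
    donor_flags: dict            # donor -> bool (any tissue p < alpha)
    m_d: dict                    # donor -> number of recorded p-values
    called: bool                 # passed the donor-majority rule
    pi0: float = 1.0
    p_fp: float = float("nan")
    accepted: bool = False
    cumulative_fdr: float = float("nan")


def donor_flags(records: list[dict], alpha: float = 0.05) -> tuple[dict, dict]:
    """Per-donor significance flags and p-value counts for one cell type.

    ``records`` holds one dict per stratum with keys donor, tissue and
    p_values (every p recorded for that stratum, one per dimension tested).
    A donor flags when ANY of its tissue strata has min recorded p < alpha;
    m_d counts all recorded p-values of that donor.
    """
    flags: dict[str, bool] = {}
    m_d: dict[str, int] = {}
    for rec in records:
        ps = list(rec["p_values"])
        if not ps:
            raise ValueError(f"stratum {rec.get('tissue')} has no recorded p-values")
        donor = rec["donor"]
        flags[donor] = flags.get(donor, False) or min(ps) < alpha
        m_d[donor] = m_d.get(donor, 0) + len(ps)
    return flags, m_d


def estimate_pi0(pvalues, lam: float = 0.5) -> float:
    """Storey estimator pi0 = #{p > lambda} / ((1 - lambda) m), clipped to (0, 1].

    Conservative fallback pi0 = 1 (with a warning) below 20 p-values.
    """
    p = np.asarray(list(pvalues), float)
    if p.size < 20:
        logger.warning("estimate_pi0: only %d p-values; returning pi0 = 1", p.size)
        return 1.0
    pi0 = (p > lam).sum() / ((1.0 - lam) * p.size)
    return float(min(max(pi0, 1e-12), 1.0))


def poisson_binomial_tail(probs, threshold: int) -> float:
    """P(X >= threshold) for X a sum of independent Bernoulli(probs), exact DP."""
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for i, q in enumerate(probs):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - q) + pmf[: i + 1] * q
        pmf[0] *= 1 - q
    return float(pmf[threshold:].sum())


def false_positive_probability(
    m_d, alpha: float = 0.05, pi0: float = 1.0
) -> float:
    """P(a null cell type passes the donor-majority rule).

    ``m_d`` is the per-donor count of recorded p-values. Each donor's null
    flag probability is 1 - (1 - pi0*alpha)^{m_d}; the majority threshold is
    ceil(D/2) donors.
    """
    m_list = list(m_d.values()) if isinstance(m_d, dict) else list(m_d)
    D = len(m_list)
    if D < 1:
        raise ValueError("need at least one donor")
    rate = pi0 * alpha
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"pi0 * alpha = {rate} outside [0, 1]")
    q = [1.0 - (1.0 - rate) ** m for m in m_list]
    return poisson_binomial_tail(q, math.ceil(D / 2))


def aggregate_cell_types(
    fit_records: dict,
    alpha: float = 0.05,
    fdr_cap: float = 0.10,
    pi0: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full aggregation: donor flags -> pi0 -> p_fp -> FDR-capped acceptance.

    ``fit_records`` maps cell_type -> list of stratum record dicts (see
    :func:`donor_flags`). pi0 is estimated from the pooled recorded p-values
    unless given. Returns (summary table, FDR-vs-retained CDF table).
    """
    all_p = [
        p
        for records in fit_records.values()
        for rec in records
        for p in rec["p_values"]
    ]
    if pi0 is None:
        pi0 = estimate_pi0(all_p)
    results: list[CellTypeSignificance] = []
    for cell_type, records in sorted(fit_records.items()):
        flags, m_d = donor_flags(records, alpha)
        D = len(flags)
        called = sum(flags.values()) >= math.ceil(D / 2) and D > 0
        res = CellTypeSignificance(
            cell_type=cell_type,
            donors_available=D,
            donor_flags=flags,
            m_d=m_d,
            called=called,
            pi0=pi0,
        )
        if called:
            res.p_fp = false_positive_probability(m_d, alpha=alpha, pi0=pi0)
        results.append(res)

    called = [r for r in results if r.called]
    accepted, total_fdr, cdf = accept_cell_types(
        {r.cell_type: r.p_fp for r in called}, fdr_cap
    )
    for r in results:
        r.accepted = r.cell_type in accepted
        if r.accepted:
            r.cumulative_fdr = total_fdr
    summary = pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "donors_available": [r.donors_available for r in results],
            "n_donors_flagged": [sum(r.donor_flags.values()) for r in results],
            "n_pvalues": [sum(r.m_d.values()) for r in results],
            "pi0": [r.pi0 for r in results],
            "called": [r.called for r in results],
            "p_fp": [r.p_fp for r in results],
            "accepted": [r.accepted for r in results],
            "total_fdr": [r.cumulative_fdr for r in results],
        }
    )
    return summary, cdf


def accept_cell_types(p_fp: dict, fdr_cap: float = 0.10) -> tuple[set, float, pd.DataFrame]:
    """Accept the largest ascending-p_fp prefix with mean p_fp below the cap.

    The total FDR of the accepted set is the mean p_fp (expected false
    positives over accepted count). Also returns the FDR-vs-retained CDF.
    Empty input yields an empty set and FDR 0 (reported with a note).
    """
    if not p_fp:
        logger.info("accept_cell_types: no called cell types; FDR undefined (0)")
        return set(), 0.0, pd.DataFrame(columns=["n_retained", "cell_type", "fdr"])
    items = sorted(p_fp.items(), key=lambda kv: (kv[1], kv[0]))
    running, rows = 0.0, []
    accepted: set = set()
    best_fdr = 0.0
    for i, (ct, p) in enumerate(items, start=1):
        running += p
        fdr = running / i
        rows.append({"n_retained": i, "cell_type": ct, "fdr": fdr})
        if fdr < fdr_cap:
            accepted = {c for c, _ in items[:i]}
            best_fdr = fdr
    return accepted, best_fdr, pd.DataFrame(rows)
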