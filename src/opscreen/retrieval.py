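"""Mean average precision (mAP) profile-strength metric.

Replicate retrieval: each of a gene's M guide profiles serves once as
the query; the remaining M-1 sibling profiles plus N control profiles
are ranked by decreasing cosine similarity to the query, and the
non-interpolated average precision rewards sibling profiles appearing
near the top. With precision P_k = TP_k / k and recall R_k =
TP_k / (M - 1) at rank k,

    AP_i = sum_k P_k * (R_k - R_{k-1}),

i.e. precision accumulated at the ranks where recall increases (the
ranks holding siblings), and mAP is the mean AP over the M queries. A
gene whose guides are phenotypically coherent against the control
background scores near 1; an exchangeable group scores at the
permutation-null level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import ProfileTable


@dataclass
class QueryResult:
    """Rank bookkeeping for one query profile."""

    ap: float
    is_match: np.ndarray  # sorted by decreasing similarity
    tp_k: np.ndarray
    precision_k: np.ndarray
    recall_k: np.ndarray


@dataclass
class RetrievalResult:
    M: int
    N: int
    per_query: list[QueryResult]

    @property
    def mAP(self) -> float:
        return float(np.mean([q.ap for q in self.per_query]))


def _cosine_to(query: np.ndarray, others: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(query)
    on = np.linalg.norm(others, axis=1)
    if qn == 0.0 or np.any(on == 0.0):
        raise ValueError("zero-norm profile")
    return (others @ query) / (on * qn)


def average_precision(
    query: np.ndarray, siblings: np.ndarray, controls: np.ndarray
) -> QueryResult:
    """Non-interpolated AP of one query against its M-1 siblings ranked
    among N controls by cosine similarity.

    Ties in similarity are broken by stable input order (siblings first,
    then controls, each in the order given).
    """
    siblings = np.atleast_2d(np.asarray(siblings, dtype=float))
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    query = np.asarray(query, dtype=float)
    m_minus_1 = siblings.shape[0]
    if m_minus_1 < 1:
        raise ValueError("need at least one sibling profile (M >= 2)")
    if controls.shape[0] < 1:
        raise ValueError("need at least one control profile (N >= 1)")
    pool = np.vstack([siblings, controls])
    sims = _cosine_to(query, pool)
    order = np.argsort(-sims, kind="stable")
    is_match = order < m_minus_1
    tp = np.cumsum(is_match)
    k = np.arange(1, len(pool) + 1)
    precision = tp / k
    recall = tp / m_minus_1
    ap = float(precision[is_match].sum() / m_minus_1)
    return QueryResult(ap, is_match, tp, precision, recall)


def map_score(group: np.ndarray, controls: np.ndarray) -> RetrievalResult:
    """mAP of a group of M profiles (each member queried once against
    its siblings and the N controls)."""
    group = np.atleast_2d(np.asarray(group, dtype=float))
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    M = group.shape[0]
    if M < 2:
        raise ValueError("query group must contain at least 2 profiles")
    per_query = []
    for i in range(M):
        siblings = np.delete(group, i, axis=0)
        per_query.append(average_precision(group[i], siblings, controls))
    return RetrievalResult(M=M, N=controls.shape[0], per_query=per_query)


def screen_map_scores(
    guide_profiles: ProfileTable,
    control_gene: str = "nontargeting",
    genes=None,
) -> pd.DataFrame:
    """Per-gene mAP over a guide-level profile table, using the
    nontargeting guide profiles as controls."""
    frame = guide_profiles.frame
    features = guide_profiles.features
    is_control = frame["Metadata_gene"] == control_gene
    controls = frame.loc[is_control, features].to_numpy(dtype=float)
    rows = []
    for gene, sub in frame.loc[~is_control].groupby("Metadata_gene", sort=True):
        if genes is not None and gene not in set(genes):
            continue
        if len(sub) < 2:
            continue
        res = map_score(sub[features].to_numpy(dtype=float), controls)
        rows.append({"gene": gene, "mAP": res.mAP, "M": res.M, "N": res.N})
    return pd.DataFrame(rows).set_index("gene")
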