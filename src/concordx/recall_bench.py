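"""Cross-study matched-drug recall benchmark.

Two studies assaying overlapping drugs on overlapping cell lines are
compared by asking, for each drug present in both, how highly its own
response profile in study B ranks among all study-B drugs when similarity
is computed against its study-A profile. A normalized rank of 0 means the
matched drug was the most similar; 1 the least. The area under the eCDF of
these ranks, which equals 1 minus their mean, summarizes cross-study
replicability: 1 for perfect recall, 0.5 for no correspondence.

Sensitivity matrices are pandas DataFrames (rows = drugs, columns = cell
lines, values AAC-like in [0, 1], NaN = missing).
"""

from __future__ import annotations

from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .core_stats import (
    PairedSample,
    RobustThresholds,
    SigmoidKernel,
    concordance_index,
    kci,
    pearson_r,
    rci_fast,
    spearman_rho,
)
from .exceptions import ConcordxError, InvalidInputError

__all__ = [
    "load_sensitivity_csv",
    "validate_sensitivity_matrix",
    "matched_drug_ranks",
    "rank_ecdf_auc",
]


def validate_sensitivity_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise InvalidInputError("drug and cell-line labels must be unique")
    vals = df.to_numpy(dtype=np.float64)
    finite = np.isfinite(vals)
    if ((vals < 0) & finite).any() or ((vals > 1) & finite).any():
        raise InvalidInputError("sensitivities must lie in [0, 1] (or be missing)")
    return df.astype(np.float64)


def load_sensitivity_csv(path) -> pd.DataFrame:
    """Read a drug x cell-line matrix: first column ``drug_id``, remaining
    columns cell-line IDs, empty cells = missing."""
    df = pd.read_csv(path, index_col=0)
    return validate_sensitivity_matrix(df)


def _similarity_fn(method, thresholds, kernel) -> Callable[[PairedSample], float]:
    if callable(method):
        return method
    name = str(method).lower()
    if name == "pearson":
        return pearson_r
    if name == "spearman":
        return spearman_rho
    if name == "ci":
        return concordance_index
    if name == "rci":
        t = thresholds or RobustThresholds()
        return lambda s: rci_fast(s, t)
    if name == "kci":
        if kernel is None:
            raise InvalidInputError("kCI needs a kernel")
        return lambda s: kci(s, kernel)
    raise InvalidInputError(f"unknown similarity method {method!r}")


def matched_drug_ranks(
    study_a: pd.DataFrame,
    study_b: pd.DataFrame,
    method: Union[str, Callable[[PairedSample], float]] = "pearson",
    min_common_lines: int = 2,
    thresholds: Optional[RobustThresholds] = None,
    kernel: Optional[SigmoidKernel] = None,
) -> pd.DataFrame:
    """Normalized rank of every matched drug across two studies.

    For each drug in A also present in B: restrict each drug pair to the
    cell lines present in both studies with values observed on both sides,
    compute the similarity of the A-profile to every B-profile, and rank
    the matched drug with mid-rank ties over the other B drugs:
    rank = (#{strictly more similar} + ties/2) / (#scored B drugs - 1).
    Matched drugs with fewer than ``min_common_lines`` pairwise-complete
    common lines are excluded; B drugs whose similarity is undefined are
    dropped from that drug's comparison set and counted in ``n_failed``.
    """
    study_a = validate_sensitivity_matrix(study_a)
    study_b = validate_sensitivity_matrix(study_b)
    common_lines = study_a.columns.intersection(study_b.columns)
    common_drugs = study_a.index.intersection(study_b.index)
    if len(common_lines) < 2 or len(common_drugs) < 1:
        raise InvalidInputError("need >= 2 common cell lines and a common drug")
    if len(study_b.index) < 2:
        raise InvalidInputError("study B must contain >= 2 drugs to rank against")
    sim = _similarity_fn(method, thresholds, kernel)
    A = study_a[common_lines]
    B = study_b[common_lines]

    rows = []
    for drug in common_drugs:
        a_vals = A.loc[drug].to_numpy()
        b_self = B.loc[drug].to_numpy()
        n_common = int((~np.isnan(a_vals) & ~np.isnan(b_self)).sum())
        if n_common < max(min_common_lines, 2):
            continue
        sims = {}
        failed = 0
        for other in B.index:
            b_vals = B.loc[other].to_numpy()
            ok = ~np.isnan(a_vals) & ~np.isnan(b_vals)
            if ok.sum() < 2:
                failed += 1
                continue
            try:
                sims[other] = sim(PairedSample(a_vals[ok], b_vals[ok]))
            except ConcordxError:
                failed += 1
        if drug not in sims or len(sims) < 2:
            continue
        self_sim = sims[drug]
        others = np.array([v for k, v in sims.items() if k != drug])
        more = int((others > self_sim).sum())
        ties = int((others == self_sim).sum())
        rank = (more + 0.5 * ties) / others.size
        rows.append(
            dict(
                drug_id=drug,
                n_common_lines=n_common,
                similarity=self_sim,
                normalized_rank=rank,
                n_compared=others.size,
                n_failed=failed,
            )
        )
    if not rows:
        raise InvalidInputError(
            "no matched drug passed the common-line threshold"
        )
    return pd.DataFrame(rows)


def rank_ecdf_auc(ranks) -> float:
    """Area under the eCDF of normalized ranks on [0, 1] = 1 - mean rank."""
    r = np.asarray(ranks, dtype=np.float64).ravel()
    if r.size == 0:
        raise InvalidInputError("empty rank vector")
    if (r < 0).any() or (r > 1).any():
        raise InvalidInputError("ranks must lie in [0, 1]")
    return float(1.0 - r.mean())
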