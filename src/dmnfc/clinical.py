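"""Clinical association of connectivity with cognitive severity.

After the network-based statistic has identified altered components, each
subject gets a composite Z score (mean Fisher-z over a component's edges);
composites and single edges are compared between groups with pooled
two-sample t tests and correlated with the MMSE score, pooling patients
and controls, via Pearson correlation with the exact t-transform p-value
(df = n - 2).  No multiple-comparison correction is applied to the
association p-values; they describe effects already selected by the
FWE-controlled network test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix
from .nbs import NbsResult


@dataclass
class ClinicalAssociation:
    """Pearson association of an edge or component Z with MMSE."""

    target: str
    r_pearson: float
    p_value: float
    n_subjects: int

    @property
    def direction(self) -> str:
        return "positive" if self.r_pearson >= 0 else "negative"


def composite_z(
    z_matrix: np.ndarray, edge_set: Sequence[tuple[int, int]]
) -> float:
    """Unweighted mean Fisher-z over the listed edges (1-based ROI pairs)."""
    if len(edge_set) == 0:
        raise ValueError("edge set must be nonempty")
    z = np.asarray(z_matrix)
    p = z.shape[0]
    vals = []
    for i, j in edge_set:
        if not (1 <= i <= p and 1 <= j <= p) or i == j:
            raise ValueError(f"invalid edge ({i}, {j}) for {p} ROIs")
        vals.append(z[i - 1, j - 1])
    return float(np.mean(vals))


def group_compare_composite(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance two-sample t and two-sided p for composite scores."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mmse_correlation(
    z_values: Sequence[float], mmse_scores: Sequence[float],
    target: str = "",
) -> ClinicalAssociation:
    """Pearson correlation of per-subject Z with MMSE, pooled over groups.

    The two-sided p comes from the exact t transform of r with df = n - 2.
    """
    z = np.asarray(z_values, dtype=float)
    m = np.asarray(mmse_scores, dtype=float)
    if z.shape != m.shape:
        raise ValueError("z values and MMSE scores must be paired")
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(m) == 0:
        raise ValueError("MMSE is constant; correlation undefined")
    r, p = stats.pearsonr(z, m)
    return ClinicalAssociation(
        target=target, r_pearson=float(r), p_value=float(p), n_subjects=n
    )


def associate_all(
    nbs_results: Mapping[str, NbsResult],
    matrices: Sequence[ConnectivityMatrix],
    participants: pd.DataFrame,
    mmse_column: str = "MMSE",
    per_group: bool = False,
) -> pd.DataFrame:
    """Associate every significant edge and component with MMSE, per band.

    ``nbs_results`` maps band name -> NbsResult; ``matrices`` holds the
    subject x band Fisher-z matrices the NBS was run on; ``participants``
    carries participant_id, group and the MMSE column.  One row is emitted
    per significant edge and one per significant-component composite.
    By default the correlation pools both groups (``per_group=False``).
    """
    part = participants.set_index("participant_id")
    by_band: dict[str, dict[str, np.ndarray]] = {}
    for m in matrices:
        by_band.setdefault(m.band, {})[m.subject_id] = m.z
    rows = []
    for band, result in nbs_results.items():
        zmaps = by_band.get(band, {})
        subjects = [s for s in zmaps if s in part.index]
        if not subjects:
            continue
        mmse = part.loc[subjects, mmse_column].to_numpy(dtype=float)
        groups = part.loc[subjects, "group"]
        group_iters = (
            [(g, groups == g) for g in groups.unique()]
            if per_group
            else [("all", pd.Series(True, index=groups.index))]
        )
        for tail, comp in result.significant_components():
            targets = [(f"edge_{i}_{j}", [(i, j)]) for i, j in comp.edges]
            targets.append(
                (f"component_{tail}_k{comp.size_k}", comp.edges)
            )
            for name, edges in targets:
                zvals = np.array(
                    [composite_z(zmaps[s], edges) for s in subjects]
                )
                for gname, sel in group_iters:
                    sel = np.asarray(sel)
                    assoc = mmse_correlation(
                        zvals[sel], mmse[sel], target=name
                    )
                    rows.append(
                        {
                            "band": band,
                            "tail": tail,
                            "target": name,
                            "scope": gname,
                            "r": assoc.r_pearson,
                            "p": assoc.p_value,
                            "n": assoc.n_subjects,
                            "direction": assoc.direction,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["band", "tail", "target", "scope", "r", "p", "n",
                 "direction"],
    )
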