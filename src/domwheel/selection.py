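"""PCA-based screening of composition measures and wheel-axis selection.

The workflow: restrict the metric table to complete cases, standardize each
column (zero mean, unit variance), run PCA, express each variable's
contribution to a component as

    contrib(j, k) = 100 * loading(j, k)^2 / sum_j loading(j, k)^2

and combine contributions to the first two components with eigenvalue
weights.  Axes are then chosen one per analytical-method family
(absorbance magnitude, absorbance shape, size exclusion, stoichiometry) so
the four wheel axes rest on different measurement principles and stay
quasi-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

#: Analytical-method families used for quasi-independence screening.
METHOD_FAMILIES = (
    "absorbance_magnitude",
    "absorbance_shape",
    "size_exclusion",
    "stoichiometry",
)

#: Default family assignment for the standard metric table columns.
DEFAULT_FAMILY_MAP = {
    "suva": "absorbance_magnitude",
    "sac350": "absorbance_magnitude",
    "sac420": "absorbance_magnitude",
    "s275_295": "absorbance_shape",
    "s350_400": "absorbance_shape",
    "sr": "absorbance_shape",
    "e2e3": "absorbance_shape",
    "e4e6": "absorbance_shape",
    "bp": "size_exclusion",
    "hsf": "size_exclusion",
    "bb": "size_exclusion",
    "lmwn": "size_exclusion",
    "lmwa": "size_exclusion",
    "hs_mw": "size_exclusion",
    "doc_don": "stoichiometry",
}

#: Metric table columns entering the PCA by default (composition measures
#: only; DOC itself is a concentration, not a composition measure).
DEFAULT_PCA_COLUMNS = list(DEFAULT_FAMILY_MAP)


@dataclass(frozen=True)
class PCAResult:
    """Standardized-variable PCA with variable contributions.

    ``loadings`` are unit eigenvectors (variables x components),
    ``eigenvalues`` the component variances, ``var_explained`` percentages
    summing to 100, ``contributions`` percentages per component summing to
    100, and ``combined_contrib_12`` the eigenvalue-weighted combination
    over PC1 and PC2.
    """

    columns: tuple[str, ...]
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    var_explained: np.ndarray
    scores: pd.DataFrame
    contributions: pd.DataFrame
    combined_contrib_12: pd.Series
    n_samples: int


def run_pca(metric_table: pd.DataFrame, columns: list[str] | None = None) -> PCAResult:
    """PCA of standardized composition measures (complete cases only).

    Columns are centered and scaled to unit variance, so the decomposition
    is of the correlation structure.  Component signs are fixed so each
    component's largest-magnitude loading is positive, making the result
    deterministic and row-order invariant.
    """
    if columns is None:
        columns = [c for c in DEFAULT_PCA_COLUMNS if c in metric_table.columns]
    missing = [c for c in columns if c not in metric_table.columns]
    if missing:
        raise ValueError(f"metric table lacks requested columns {missing}")

    sub = metric_table[columns].dropna(axis=0, how="any")
    n, p = sub.shape
    logger.info("PCA complete-case subset: n = %d of %d samples, %d variables",
                n, len(metric_table), p)
    if n < p:
        raise ValueError(
            f"only {n} complete rows for {p} columns; PCA needs at least as "
            "many complete samples as variables"
        )
    X = sub.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=1)
    zero = [columns[j] for j in np.flatnonzero(std == 0)]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    Z = (X - X.mean(axis=0)) / std

    pca = _SKPCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components, unit columns

    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0

    eigenvalues = pca.explained_variance_
    var_explained = 100.0 * pca.explained_variance_ratio_
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]

    load_df = pd.DataFrame(loadings, index=columns, columns=comp_names)
    contrib = 100.0 * load_df**2 / (load_df**2).sum(axis=0)
    lam1, lam2 = eigenvalues[0], eigenvalues[1] if len(eigenvalues) > 1 else 0.0
    combined = (contrib["PC1"] * lam1 + (contrib["PC2"] * lam2 if "PC2" in contrib else 0.0)) / (
        lam1 + lam2
    )
    combined.name = "combined_contrib_12"

    return PCAResult(
        columns=tuple(columns),
        loadings=load_df,
        eigenvalues=np.asarray(eigenvalues),
        var_explained=np.asarray(var_explained),
        scores=pd.DataFrame(scores, index=sub.index, columns=comp_names),
        contributions=contrib,
        combined_contrib_12=combined,
        n_samples=n,
    )


def contributions(pca_result: PCAResult) -> pd.DataFrame:
    """Per-variable contributions (%) to each component.

    Includes the eigenvalue-weighted PC1+PC2 combination as a final column.
    """
    out = pca_result.contributions.copy()
    out["combined_12"] = pca_result.combined_contrib_12
    return out


@dataclass(frozen=True)
class AxisSelection:
    """Four wheel axes, one per analytical-method family."""

    metrics: tuple[str, ...]
    families: dict[str, str] = field(hash=False)
    contributions: dict[str, float] = field(hash=False)
    threshold_pct: float = 2.0
    fallback_families: tuple[str, ...] = ()

    def __post_init__(self):
        fams = [self.families[m] for m in self.metrics]
        if len(set(fams)) != len(fams):
            raise ValueError("selected metrics must come from distinct families")


def select_axes(
    pca_result: PCAResult,
    family_map: dict[str, str] | None = None,
    threshold_pct: float = 2.0,
    n_axes: int = 4,
) -> AxisSelection:
    """Pick one high-contribution variable per analytical-method family.

    Variables with combined PC1+PC2 contribution below ``threshold_pct``
    are screened out *within* each family; a family whose members all fall
    below the threshold falls back to its highest contributor with a warning
    (independence of measurement principle outranks raw contribution).  If
    no variable at all survives the threshold, that is an error.  Ties are
    broken alphabetically and logged.
    """
    if family_map is None:
        family_map = {c: DEFAULT_FAMILY_MAP[c] for c in pca_result.columns
                      if c in DEFAULT_FAMILY_MAP}
    uncovered = [c for c in pca_result.columns if c not in family_map]
    if uncovered:
        raise ValueError(f"family_map does not cover columns {uncovered}")

    combined = pca_result.combined_contrib_12
    if not (combined >= threshold_pct).any():
        raise ValueError(
            f"no variable reaches the {threshold_pct}% combined PC1+PC2 "
            "contribution threshold; nothing survives screening"
        )

    by_family: dict[str, list[str]] = {}
    for col in pca_result.columns:
        by_family.setdefault(family_map[col], []).append(col)
    if len(by_family) < n_axes:
        raise ValueError(
            f"need {n_axes} distinct method families, found "
            f"{sorted(by_family)}"
        )

    # rank candidate per family: highest contribution, alphabetical tie-break
    def best(members: list[str]) -> str:
        ranked = sorted(members, key=lambda m: (-combined[m], m))
        if len(ranked) > 1 and combined[ranked[0]] == combined[ranked[1]]:
            logger.info(
                "tie at %.3f%% between %s; broken alphabetically -> %s",
                combined[ranked[0]], ranked[:2], ranked[0],
            )
        return ranked[0]

    chosen: list[str] = []
    fallbacks: list[str] = []
    family_best: dict[str, str] = {}
    for fam, members in by_family.items():
        surviving = [m for m in members if combined[m] >= threshold_pct]
        if surviving:
            family_best[fam] = best(surviving)
        else:
            pick = best(members)
            logger.warning(
                "family %r has no variable above %.2f%% contribution; "
                "falling back to its highest contributor %r (%.3f%%)",
                fam, threshold_pct, pick, combined[pick],
            )
            family_best[fam] = pick
            fallbacks.append(fam)

    # order families by their best member's contribution (descending)
    fams_ranked = sorted(
        family_best, key=lambda f: (-combined[family_best[f]], f)
    )[:n_axes]
    chosen = [family_best[f] for f in fams_ranked]

    return AxisSelection(
        metrics=tuple(chosen),
        families={m: family_map[m] for m in chosen},
        contributions={m: float(combined[m]) for m in chosen},
        threshold_pct=threshold_pct,
        fallback_families=tuple(fallbacks),
    )
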