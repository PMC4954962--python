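"""Replicate-based hit calling with an expression-level confounder control.

A mutant is a hit when (1) its replicate inclusion percentages differ from
wild type at P <= 0.05 by two-sample Student's t-test, (2) the effect is at
least 25% (by default relative to the wild-type percentage), and (3) its
fluorescence intensity does NOT differ significantly — strains failing the
third criterion are routed to an "expression_confounded" category rather
than being reported as hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

CATEGORIES = ("decreased", "increased", "expression_confounded", "not_hit")


@dataclass
class StrainPhenotype:
    """Replicate phenotype measurements for one strain."""

    strain_id: str
    gene_id: str
    construct: str
    pct_inclusion: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.pct_inclusion = np.asarray(self.pct_inclusion, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.pct_inclusion.shape != self.mean_intensity.shape:
            raise ValueError("replicate counts differ between measures")
        if np.any((self.pct_inclusion < 0) | (self.pct_inclusion > 100)):
            raise ValueError("percentages must lie in [0, 100]")

    @property
    def n_replicates(self) -> int:
        return len(self.pct_inclusion)


@dataclass
class HitCriteria:
    """Thresholds for the three hit-calling rules.

    ``min_effect`` is interpreted per ``effect_mode``: with
    ``"relative_to_wt"`` (default) the mutant percentage must change by at
    least ``min_effect`` percent OF the wild-type value; with
    ``"absolute_points"`` by at least ``min_effect`` percentage points.
    """

    alpha_inclusion: float = 0.05
    min_effect: float = 25.0
    effect_mode: str = "relative_to_wt"
    alpha_intensity: float = 0.05

    def __post_init__(self) -> None:
        for alpha in (self.alpha_inclusion, self.alpha_intensity):
            if not 0 < alpha <= 1:
                raise ValueError("alpha must be in (0, 1]")
        if self.min_effect <= 0:
            raise ValueError("min_effect must be > 0")
        if self.effect_mode not in ("relative_to_wt", "absolute_points"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


@dataclass
class HitCall:
    """Per-strain classification with test statistics and effect size."""

    strain_id: str
    category: str
    p_inclusion: float
    p_intensity: float
    effect: float  # signed, percent (see HitCriteria.effect_mode)
    normalized_pct: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def students_t(a, b) -> tuple[float, float]:
    """Two-sample equal-variance Student's t with a two-sided p-value.

    Degenerate zero-variance input maps to (0, 1) for equal means and to
    (+/-inf, 0) for unequal means (flagged in the log).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        log.warning("students_t: zero pooled variance with unequal means")
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def normalize_to_wt(pct_mut: float, pct_wt: float) -> float:
    """Anchor a mutant percentage to a 50%-wild-type scale (uncapped)."""
    if pct_wt <= 0:
        raise ValueError("wild-type percentage must be > 0 to normalize")
    return 50.0 * pct_mut / pct_wt


def _effect(mean_mut: float, mean_wt: float, criteria: HitCriteria) -> float:
    if criteria.effect_mode == "relative_to_wt":
        if mean_wt <= 0:
            raise ValueError("relative effect undefined for non-positive WT mean")
        return 100.0 * (mean_mut - mean_wt) / mean_wt
    return mean_mut - mean_wt


def call_hits(
    mutants: list[StrainPhenotype],
    wt: StrainPhenotype,
    criteria: HitCriteria | None = None,
) -> list[HitCall]:
    """Classify each mutant against the wild-type reference.

    Rules: significant inclusion change with sufficient effect and no
    significant intensity change -> "decreased"/"increased" by sign;
    significant inclusion change accompanied by a significant intensity
    change -> "expression_confounded"; anything else -> "not_hit".
    Strains with fewer than 2 replicates are skipped with a log entry.
    """
    if wt is None:
        raise ValueError("wild-type reference is required")
    if wt.n_replicates < 2:
        raise ValueError("wild-type needs at least 2 replicates")
    criteria = criteria or HitCriteria()
    calls: list[HitCall] = []
    wt_pct_mean = float(wt.pct_inclusion.mean())
    for mutant in mutants:
        if mutant.n_replicates < 2:
            log.warning("skipping %s: fewer than 2 replicates", mutant.strain_id)
            continue
        _, p_inc = students_t(mutant.pct_inclusion, wt.pct_inclusion)
        _, p_int = students_t(mutant.mean_intensity, wt.mean_intensity)
        effect = _effect(float(mutant.pct_inclusion.mean()), wt_pct_mean, criteria)
        significant_inc = p_inc <= criteria.alpha_inclusion
        big_enough = abs(effect) >= criteria.min_effect
        intensity_clean = p_int > criteria.alpha_intensity
        if significant_inc and not intensity_clean:
            category = "expression_confounded"
        elif significant_inc and big_enough and intensity_clean:
            category = "decreased" if effect < 0 else "increased"
        else:
            category = "not_hit"
        calls.append(
            HitCall(
                strain_id=mutant.strain_id,
                category=category,
                p_inclusion=p_inc,
                p_intensity=p_int,
                effect=effect,
                normalized_pct=normalize_to_wt(
                    float(mutant.pct_inclusion.mean()), wt_pct_mean
                ),
            )
        )
    return calls


def confirmation_rate(
    automated_hits: set[str], manually_confirmed: set[str]
) -> tuple[float, float]:
    """Percent of automated hits that survive manual inspection.

    Returns (confirmation_pct, false_positive_pct); the confirmed set must
    be a subset of the automated set.
    """
    automated = set(automated_hits)
    confirmed = set(manually_confirmed)
    if not automated:
        raise ValueError("automated hit set is empty")
    if not confirmed <= automated:
        raise ValueError("confirmed hits must be a subset of automated hits")
    pct = 100.0 * len(confirmed) / len(automated)
    return pct, 100.0 - pct


@dataclass
class BackgroundRegistry:
    """Deduplicated screening-collection registry.

    ``n_strains`` counts manifest rows (ts alleles of the same gene count
    separately); the gene universe collapses them.
    """

    n_strains: int
    gene_universe: set[str]
    deletion_genes: set[str]
    essential_genes: set[str]


def build_background_registry(
    deletion_manifest: pd.DataFrame, ts_manifest: pd.DataFrame
) -> BackgroundRegistry:
    """Combine the deletion and ts-allele collection manifests.

    Both tables must carry ``strain_id`` and ``gene_id`` columns; duplicate
    strain ids across the two arms are an error.
    """
    for name, manifest in (("deletion", deletion_manifest), ("ts", ts_manifest)):
        missing = {"strain_id", "gene_id"} - set(manifest.columns)
        if missing:
            raise ValueError(f"{name} manifest missing columns {sorted(missing)}")
    combined = pd.concat(
        [deletion_manifest["strain_id"], ts_manifest["strain_id"]], ignore_index=True
    )
    if combined.duplicated().any():
        raise ValueError("duplicate strain_id across manifests")
    deletion_genes = set(deletion_manifest["gene_id"].astype(str))
    essential_genes = set(ts_manifest["gene_id"].astype(str))
    return BackgroundRegistry(
        n_strains=len(deletion_manifest) + len(ts_manifest),
        gene_universe=deletion_genes | essential_genes,
        deletion_genes=deletion_genes,
        essential_genes=essential_genes,
    )


# ---------------------------------------------------------------------------
# table-level driver


def phenotypes_from_wells(wells: pd.DataFrame, qc_only: bool = True) -> dict[str, StrainPhenotype]:
    """Group a wells table (WellPhenotype schema) into per-strain replicates."""
    frame = wells
    if qc_only and "qc_pass" in frame.columns:
        frame = frame[frame["qc_pass"]]
    out: dict[str, StrainPhenotype] = {}
    for (strain_id, construct), grp in frame.groupby(["strain_id", "construct"]):
        out[str(strain_id)] = StrainPhenotype(
            strain_id=str(strain_id),
            gene_id=str(grp["gene_id"].iloc[0]) if "gene_id" in grp.columns else str(strain_id),
            construct=str(construct),
            pct_inclusion=grp["pct_inclusion"].to_numpy(),
            mean_intensity=grp["mean_cell_intensity"].to_numpy(),
        )
    return out


def hits_frame(calls: list[HitCall]) -> pd.DataFrame:
    """HitCall table with a supplementary Benjamini-Hochberg column.

    Hit calling itself uses raw p-values (no multiple-testing correction);
    the ``q_inclusion`` column is informational only.
    """
    frame = pd.DataFrame([vars(c) for c in calls])
    if len(frame):
        frame["q_inclusion"] = sps.false_discovery_control(
            frame["p_inclusion"].clip(upper=1.0)
        )
    return frame
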