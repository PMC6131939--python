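"""Dose-series expression analysis and a matching synthetic generator.

Expression tables are long-format: one row per (gene, genotype, dose,
replicate) measurement of already-normalized relative expression.
Correlation against the reference gene is computed over the per-condition
means (genotype x dose grid), and genes are classified co-induced when
r exceeds the threshold (0.7 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DOSES = (0.0, 12.5, 50.0, 100.0, 3000.0)
GENOTYPES = ("tolerant", "sensitive")

CO_INDUCED = "co-induced"
OTHER = "other"
CONSTANT = "constant"

RAW_COLUMNS = ["gene", "genotype", "dose", "replicate", "value"]


def summarize_replicates(raw: pd.DataFrame, allow_single: bool = False) -> pd.DataFrame:
    """Per-condition mean and sample SD from replicate measurements.

    Returns a frame indexed by (gene, genotype, dose) with columns
    ``mean``, ``sd``, ``n``.  Cells with a single replicate raise unless
    ``allow_single``; cells with fewer replicates than the fullest cell
    produce a warning.
    """
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw table missing columns {sorted(missing)}")
    grouped = raw.groupby(["gene", "genotype", "dose"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    if (out["n"] < 1).any():
        raise ValueError("empty condition cell")
    single = out["n"] < 2
    if single.any():
        if not allow_single:
            raise ValueError(
                f"{int(single.sum())} condition cells have a single replicate; "
                "pass allow_single to accept them"
            )
        out.loc[single, "sd"] = 0.0
    n_full = int(out["n"].max())
    short = out["n"] < n_full
    if short.any():
        warnings.warn(
            f"{int(short.sum())} condition cells have fewer than {n_full} replicates",
            stacklevel=2,
        )
    return out


@dataclass
class CoexpressionResult:
    reference: str
    tau: float
    table: pd.DataFrame  # per gene: r, pvalue, class
    alpha: float = 0.05

    def genes_in_class(self, cls: str) -> list[str]:
        return self.table.index[self.table["class"] == cls].tolist()


def correlate_with_reference(
    summary: pd.DataFrame,
    reference: str,
    tau: float = 0.7,
    alpha: float = 0.05,
    require_significance: bool = False,
) -> CoexpressionResult:
    """Pearson r of every gene's condition-mean profile vs the reference.

    Co-induced iff r > tau (optionally additionally p < alpha).  Genes with
    a zero-variance profile are reported as "constant" and excluded from
    the co-induced/other partition.
    """
    means = summary["mean"].unstack(["genotype", "dose"]).sort_index(axis=1)
    if reference not in means.index:
        raise KeyError(f"reference gene {reference!r} not in table")
    ref_profile = means.loc[reference].to_numpy(dtype=float)
    if np.isnan(ref_profile).any():
        raise ValueError("reference profile has missing conditions")
    if np.std(ref_profile) == 0:
        raise ValueError("reference profile is constant; correlation undefined")

    rows = []
    for gene in means.index:
        if gene == reference:
            continue
        prof = means.loc[gene].to_numpy(dtype=float)
        if np.isnan(prof).any():
            raise ValueError(f"gene {gene!r} has missing conditions")
        if np.std(prof) == 0:
            rows.append((gene, np.nan, np.nan, CONSTANT))
            continue
        r, p = stats.pearsonr(ref_profile, prof)
        co = r > tau and (p < alpha if require_significance else True)
        rows.append((gene, float(r), float(p), CO_INDUCED if co else OTHER))
    table = pd.DataFrame(rows, columns=["gene", "r", "pvalue", "class"]).set_index("gene")
    return CoexpressionResult(reference, tau, table, alpha)


@dataclass
class InductionProfile:
    """Step induction: expression jumps from baseline once dose reaches the
    genotype's threshold."""

    sensitive_threshold: float = 50.0
    tolerant_threshold: float = 3000.0
    baseline: float = 1.0
    induced: float = 8.0

    def mean(self, genotype: str, dose: float) -> float:
        threshold = (
            self.sensitive_threshold if genotype == "sensitive" else self.tolerant_threshold
        )
        return self.induced if dose >= threshold else self.baseline


def generate_expression(
    n_coregulated: int = 7,
    n_independent: int = 13,
    profile: InductionProfile | None = None,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    noise_sd: float = 0.3,
    n_replicates: int = 6,
    reference: str = "REF",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Synthetic dose-series replicate table with known co-regulation truth.

    The reference gene follows the step-induction profile (induced at and
    above 50 uM in the sensitive genotype, only at the top dose in the
    tolerant one).  Co-regulated genes ("CO01"...) share the profile up to a
    positive gene-specific scale; independent genes ("IND01"...) are flat.
    Gaussian noise of ``noise_sd`` is added to every replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    profile = profile or InductionProfile()

    co_scales = rng.uniform(0.5, 2.0, size=n_coregulated)
    ind_levels = rng.uniform(0.5, 3.0, size=n_independent)

    rows = []
    for genotype in GENOTYPES:
        for dose in doses:
            base = profile.mean(genotype, dose)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (reference, genotype, dose, rep, base + rng.normal(0, noise_sd))
                )
                for g in range(n_coregulated):
                    rows.append(
                        (
                            f"CO{g + 1:02d}", genotype, dose, rep,
                            co_scales[g] * base + rng.normal(0, noise_sd),
                        )
                    )
                for g in range(n_independent):
                    rows.append(
                        (
                            f"IND{g + 1:02d}", genotype, dose, rep,
                            ind_levels[g] + rng.normal(0, noise_sd),
                        )
                    )
    return pd.DataFrame(rows, columns=RAW_COLUMNS)
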