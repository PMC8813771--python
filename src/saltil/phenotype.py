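"""Salt-tolerance phenotype indices for hydroponic screening data.

Implements the standard seedling-stage salinity indices: relative trait
percentages (salt/control, normalised to a sensitive check line),
electrolyte leakage EL = 100 * Ec1/Ec2, tissue Na+/K+ molar ratios (with
mass-to-molar conversion), SES score distributions, and two-sample t-tests
between lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ION_TISSUES, PHENO_TRAITS, SES_LEVELS

#: Atomic masses (g/mol) used for mass -> molar conversion.
ATOMIC_MASS_NA = 22.990
ATOMIC_MASS_K = 39.098


class PhenotypeError(ValueError):
    """Raised on invalid phenotype inputs."""


def electrolyte_leakage(ec1: float, ec2: float) -> float:
    """Membrane-injury index: 100 * Ec1 / Ec2.

    Ec1 is the conductivity of the bathing solution before autoclaving the
    leaf segments, Ec2 after; the ratio is scale invariant in the
    conductivity unit. A value above 100 (Ec1 > Ec2) is physically
    inconsistent and returned with a warning.
    """
    if ec2 <= 0:
        raise PhenotypeError("Ec2 must be positive")
    if ec1 < 0:
        raise PhenotypeError("Ec1 must be non-negative")
    value = 100.0 * ec1 / ec2
    if ec1 > ec2:
        warnings.warn(
            f"Ec1 ({ec1}) exceeds Ec2 ({ec2}); EL {value:.1f} > 100",
            stacklevel=2)
    return value


def relative_trait(mean_salt: float, mean_control: float) -> float:
    """Trait retention under salt, percent of the control mean."""
    if mean_control <= 0:
        raise PhenotypeError("control mean must be positive")
    return 100.0 * mean_salt / mean_control


def normalize_to_check(rel: float, rel_check: float) -> float:
    """Fold change of a relative trait versus the sensitive check line."""
    if rel_check <= 0:
        raise PhenotypeError("check-line relative value must be positive")
    return rel / rel_check


def na_k_ratio(na_amount: float, k_amount: float, unit: str = "mol") -> float:
    """Na+/K+ molar ratio; mass-based amounts are converted with the atomic
    masses of Na (22.990) and K (39.098) before dividing."""
    if na_amount <= 0 or k_amount <= 0:
        raise PhenotypeError("ion amounts must be positive")
    if unit == "mol":
        return na_amount / k_amount
    if unit == "mass":
        return (na_amount / ATOMIC_MASS_NA) / (k_amount / ATOMIC_MASS_K)
    raise PhenotypeError(f"unknown unit {unit!r} (expected 'mol' or 'mass')")


def ses_distribution(scores) -> dict[int, float]:
    """Percentage of plants at each SES score value (1/3/5/7/9)."""
    scores = [int(s) for s in np.asarray(scores).ravel()]
    if not scores:
        raise PhenotypeError("no SES scores supplied")
    bad = sorted({s for s in scores if s not in SES_LEVELS})
    if bad:
        raise PhenotypeError(f"invalid SES scores {bad}; allowed {SES_LEVELS}")
    n = len(scores)
    return {level: 100.0 * scores.count(level) / n
            for level in SES_LEVELS if level in scores}


def significance_stars(p: float) -> str:
    """Table-footnote style stars: * P < 0.05, ** P < 0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    stars: str


def compare_lines(values_a, values_b, welch: bool = False) -> TTestResult:
    """Two-sample t-test between replicate measurements of two lines.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PhenotypeError("need at least two replicates per group")
    if np.array_equal(a, b) and np.ptp(a) == 0:
        # identical constant groups: t = 0, no evidence of difference
        return TTestResult(0.0, 1.0, "")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(p):  # zero pooled variance
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    return TTestResult(float(t), float(p), significance_stars(float(p)))


# ---------------------------------------------------------------------------
# table-level summaries
# ---------------------------------------------------------------------------

def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def tolerance_index_table(
    phenotypes: pd.DataFrame,
    check_line: str,
    traits: tuple[str, ...] = PHENO_TRAITS,
) -> pd.DataFrame:
    """Per line and trait: relative percentage (salt/control) and fold versus
    the sensitive check line.

    Replicate values are averaged per line and condition (grand means) before
    forming the ratio. The check line's own fold is 1 by construction.
    """
    if check_line not in set(phenotypes["line_id"]):
        raise PhenotypeError(f"check line {check_line!r} not in table")
    means = (phenotypes.groupby(["line_id", "condition"])[list(traits)]
             .mean())
    rows = []
    rel_check: dict[str, float] = {}
    for trait in traits:
        rel_check[trait] = relative_trait(
            means.loc[(check_line, "salt"), trait],
            means.loc[(check_line, "control"), trait])
    for line in sorted(set(phenotypes["line_id"])):
        for trait in traits:
            rel = relative_trait(means.loc[(line, "salt"), trait],
                                 means.loc[(line, "control"), trait])
            rows.append(dict(
                line_id=line, trait=trait, relative_pct=rel,
                fold_vs_check=normalize_to_check(rel, rel_check[trait])))
    return pd.DataFrame(rows)


def el_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per line: mean +/- SEM electrolyte leakage under salt."""
    salt = phenotypes[phenotypes["condition"] == "salt"]
    rows = []
    for line, sub in salt.groupby("line_id"):
        el = np.array([electrolyte_leakage(e1, e2)
                       for e1, e2 in zip(sub["Ec1"], sub["Ec2"])])
        rows.append(dict(line_id=line, el_mean=float(el.mean()),
                         el_sem=_sem(el), n=len(el)))
    return pd.DataFrame(rows)


def na_k_summary(ions: pd.DataFrame) -> pd.DataFrame:
    """Per line and tissue: mean +/- SEM Na+/K+ molar ratio."""
    rows = []
    for (line, tissue), sub in ions.groupby(["line_id", "tissue"]):
        ratios = np.array([
            na_k_ratio(na, k, unit)
            for na, k, unit in zip(sub["na_amount"], sub["k_amount"],
                                   sub["unit"])])
        rows.append(dict(line_id=line, tissue=tissue,
                         ratio_mean=float(ratios.mean()),
                         ratio_sem=_sem(ratios), n=len(ratios)))
    out = pd.DataFrame(rows)
    order = {t: i for i, t in enumerate(ION_TISSUES)}
    return out.sort_values(
        ["line_id", "tissue"],
        key=lambda s: s.map(order) if s.name == "tissue" else s,
    ).reset_index(drop=True)


def ses_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per line: SES category percentages under salt."""
    salt = phenotypes[(phenotypes["condition"] == "salt")
                      & phenotypes["SES"].notna()]
    rows = []
    for line, sub in salt.groupby("line_id"):
        dist = ses_distribution(sub["SES"].astype(int))
        for level in SES_LEVELS:
            rows.append(dict(line_id=line, ses=level,
                             pct=dist.get(level, 0.0)))
    return pd.DataFrame(rows)
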