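"""Single-instrument causal genetics: Wald-ratio MR, ABF colocalization,
credible sets, LD, and criteria-based variant prioritization.

The chain implemented here mirrors the standard post-GWAS workflow for a
single associated locus:

* **Wald ratio** — with one instrumental variant, the causal effect of the
  exposure on the outcome is beta_outcome / beta_exposure, with the
  first-order standard error se_outcome / |beta_exposure| under the NOME
  (no measurement error in the instrument-exposure association)
  assumption.  Instrument strength is the F-statistic (beta/se)^2.
* **Colocalization** — Wakefield's approximate Bayes factor per variant
  and trait, combined over the five hypotheses (no signal / trait-1 only /
  trait-2 only / two distinct causal variants / one shared causal
  variant) with priors p1, p2, p12; PP4 is the posterior that the traits
  share a causal variant, and the per-variant PP4 distributes that
  posterior over candidate variants.
* **Credible set** — the smallest set of variants whose posterior
  inclusion probabilities (from an upstream fine-mapping fit) sum to at
  least the requested coverage.
* **Prioritization** — non-coding variants need at least two lines of
  regulatory/expression evidence to remain candidates; coding
  non-synonymous variants are prioritized directly, reporting the
  fraction of effect predictors voting deleterious.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SummaryStatRecord",
    "WaldResult",
    "ColocResult",
    "CredibleSet",
    "PrioritizationRecord",
    "wald_ratio_mr",
    "wakefield_labf",
    "coloc_abf",
    "credible_set_from_pips",
    "ld_r2_matrix",
    "prioritize_variants",
    "read_summary_stats",
    "write_summary_stats",
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's marginal GWAS association for one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.variant_id}: eaf must be in (0, 1)")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.variant_id}: p must be in (0, 1]")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset(
            (self.effect_allele.upper(), self.other_allele.upper())
        ) in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class WaldResult:
    """Wald-ratio MR estimate with NOME first-order standard error."""

    ratio: float
    se_ratio: float
    p: float
    f_statistic: float


@dataclass(frozen=True)
class ColocResult:
    """ABF colocalization posteriors over the five hypotheses."""

    pp: np.ndarray  # PP0..PP4, sums to 1
    per_variant_pp4: pd.Series  # indexed by variant id, sums to 1
    priors: tuple[float, float, float]

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def lead_variant(self) -> str:
        return str(self.per_variant_pp4.idxmax())


@dataclass(frozen=True)
class CredibleSet:
    """Smallest PIP-ordered variant set reaching the coverage level."""

    members: tuple[tuple[str, float], ...]  # (variant_id, pip), decreasing pip
    coverage_level: float
    cumulative_pip: float

    @property
    def variant_ids(self) -> list[str]:
        return [v for v, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PrioritizationRecord:
    """Evidence flags for one credible-set variant.

    The four non-coding criteria are externally looked-up inputs:
    regulatory-region overlap (narrow-peak supported), a predicted
    enhancer-gene link, association with *increased* target expression,
    and colocalization with an expression/protein QTL signal.
    """

    variant_id: str
    is_coding_nonsynonymous: bool = False
    regulatory_overlap: bool = False
    re2g_link: bool = False
    increases_expression: bool = False
    qtl_colocalizes: bool = False
    deleterious_votes: int = 0
    total_predictors: int = 0
    prioritized: bool | None = None
    deleterious_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.deleterious_votes > self.total_predictors:
            raise ValueError(
                f"{self.variant_id}: deleterious_votes exceeds total_predictors"
            )

    @property
    def n_criteria_met(self) -> int:
        return sum(
            (
                self.regulatory_overlap,
                self.re2g_link,
                self.increases_expression,
                self.qtl_colocalizes,
            )
        )


def _harmonize(
    exposure: SummaryStatRecord, outcome: SummaryStatRecord
) -> SummaryStatRecord:
    """Align the outcome record to the exposure's effect allele.

    A swapped allele pair flips the outcome beta (and EAF); anything else
    is an unresolvable mismatch.  Strand-ambiguous pairs (A/T, C/G) are
    kept with a warning and a frequency sanity check when EAFs allow it.
    """
    e_eff, e_oth = exposure.effect_allele.upper(), exposure.other_allele.upper()
    o_eff, o_oth = outcome.effect_allele.upper(), outcome.other_allele.upper()
    if exposure.is_strand_ambiguous:
        msg = f"{exposure.variant_id}: strand-ambiguous alleles ({e_eff}/{e_oth})"
        if abs(exposure.eaf - 0.5) > 0.08 and abs(outcome.eaf - 0.5) > 0.08:
            agree = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
            msg += "; EAFs " + ("agree" if agree else "DISAGREE") + " on the minor allele"
        warnings.warn(msg, stacklevel=3)
    if (o_eff, o_oth) == (e_eff, e_oth):
        return outcome
    if (o_eff, o_oth) == (e_oth, e_eff):
        return replace(
            outcome,
            effect_allele=outcome.other_allele,
            other_allele=outcome.effect_allele,
            eaf=1.0 - outcome.eaf,
            beta=-outcome.beta,
        )
    raise ValueError(
        f"{exposure.variant_id}: alleles {o_eff}/{o_oth} cannot be harmonized "
        f"to {e_eff}/{e_oth}"
    )


def wald_ratio_mr(
    exposure: SummaryStatRecord, outcome: SummaryStatRecord
) -> WaldResult:
    """Single-instrument Wald-ratio causal estimate under NOME.

    ratio = beta_out / beta_exp; se = se_out / |beta_exp| (first order,
    exposure treated as measured without error); two-sided normal p-value;
    F-statistic (beta_exp / se_exp)^2 gauges instrument strength.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"different variants: {exposure.variant_id} vs {outcome.variant_id}"
        )
    if exposure.beta == 0:
        raise ZeroDivisionError(
            f"{exposure.variant_id}: exposure beta is 0 — undefined instrument"
        )
    outcome = _harmonize(exposure, outcome)
    ratio = outcome.beta / exposure.beta
    se_ratio = outcome.se / abs(exposure.beta)
    z = ratio / se_ratio
    p = float(2.0 * norm.sf(abs(z)))
    f_stat = (exposure.beta / exposure.se) ** 2
    return WaldResult(ratio=float(ratio), se_ratio=float(se_ratio), p=p, f_statistic=float(f_stat))


def wakefield_labf(
    beta: float | np.ndarray, se: float | np.ndarray, prior_sd: float
) -> float | np.ndarray:
    """Log approximate Bayes factor for one association (Wakefield).

    With z = beta/se and shrinkage r = W^2 / (W^2 + se^2) for effect prior
    N(0, W^2):  log ABF = 0.5 * (log(1 - r) + r z^2).  Positive values
    favour a real effect over the null.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    labf = 0.5 * (np.log1p(-r) + r * z * z)
    return float(labf) if labf.ndim == 0 else labf


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference underflows."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    trait1: list[SummaryStatRecord],
    trait2: list[SummaryStatRecord],
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.2,
    prior_sd2: float = 0.2,
) -> ColocResult:
    """Single-signal ABF colocalization of two traits over a shared region.

    Both trait lists must cover the same variants; trait 2 records are
    allele-harmonized to trait 1 (harmonization does not change |z|, so
    posteriors are flip-invariant, but it keeps the records coherent).
    Hypothesis sums are accumulated in log space.
    """
    if len(trait1) < 2:
        raise ValueError("colocalization needs at least 2 shared variants")
    ids1 = [r.variant_id for r in trait1]
    if len(set(ids1)) != len(ids1):
        raise ValueError("duplicate variant ids in trait 1")
    by_id2 = {r.variant_id: r for r in trait2}
    if len(by_id2) != len(trait2):
        raise ValueError("duplicate variant ids in trait 2")
    if set(ids1) != set(by_id2):
        raise ValueError("traits do not cover the same variant set")
    aligned2 = [_harmonize(r1, by_id2[r1.variant_id]) for r1 in trait1]

    l1 = wakefield_labf(
        np.array([r.beta for r in trait1]),
        np.array([r.se for r in trait1]),
        prior_sd1,
    )
    l2 = wakefield_labf(
        np.array([r.beta for r in aligned2]),
        np.array([r.se for r in aligned2]),
        prior_sd2,
    )
    lsum = l1 + l2
    lse1 = float(logsumexp(l1))
    lse2 = float(logsumexp(l2))
    lse12 = float(logsumexp(lsum))

    lh = np.array(
        [
            0.0,
            math.log(p1) + lse1,
            math.log(p2) + lse2,
            math.log(p1) + math.log(p2) + _log_diff_exp(lse1 + lse2, lse12),
            math.log(p12) + lse12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    per_variant = np.exp(lsum - lse12)
    per_variant /= per_variant.sum()
    return ColocResult(
        pp=pp,
        per_variant_pp4=pd.Series(per_variant, index=ids1),
        priors=(p1, p2, p12),
    )


def credible_set_from_pips(
    pips: dict[str, float], coverage: float = 0.95
) -> CredibleSet:
    """Smallest variant set whose PIPs cumulate to at least ``coverage``.

    Variants are taken in decreasing PIP order (ties broken by lexicographic
    variant id) until the running sum reaches the coverage level; the
    resulting set is minimal by construction.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    for v, pip in pips.items():
        if not 0 <= pip <= 1:
            raise ValueError(f"{v}: PIP {pip} outside [0, 1]")
    total = sum(pips.values())
    if total < coverage - 1e-12:
        raise ValueError(
            f"total PIP {total:.4f} cannot reach coverage {coverage} "
            f"(achievable coverage: {total:.4f})"
        )
    ordered = sorted(pips.items(), key=lambda kv: (-kv[1], kv[0]))
    members: list[tuple[str, float]] = []
    cumulative = 0.0
    for variant, pip in ordered:
        members.append((variant, pip))
        cumulative += pip
        if cumulative >= coverage - 1e-12:
            break
    return CredibleSet(
        members=tuple(members),
        coverage_level=coverage,
        cumulative_pip=cumulative,
    )


def ld_r2_matrix(genotypes: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation of allele dosages (samples x variants)."""
    if isinstance(genotypes, pd.DataFrame):
        names = list(genotypes.columns)
        X = genotypes.to_numpy(dtype=float)
    else:
        X = np.asarray(genotypes, dtype=float)
        names = [f"v{i+1}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=0)
    mono = [names[j] for j in np.flatnonzero(sd == 0)]
    if mono:
        raise ValueError(f"monomorphic variants: {mono}")
    r2 = np.corrcoef(X, rowvar=False) ** 2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=names, columns=names)


def prioritize_variants(
    records: list[PrioritizationRecord],
) -> list[PrioritizationRecord]:
    """Apply the prioritization rule and return annotated copies.

    Non-coding variants are prioritized iff at least two of the four
    evidence criteria hold.  Coding non-synonymous variants are
    prioritized directly, with the deleterious predictor fraction
    (votes / total) attached.
    """
    out = []
    for rec in records:
        if rec.is_coding_nonsynonymous:
            fraction = (
                rec.deleterious_votes / rec.total_predictors
                if rec.total_predictors > 0
                else None
            )
            out.append(replace(rec, prioritized=True, deleterious_fraction=fraction))
        else:
            out.append(
                replace(
                    rec,
                    prioritized=rec.n_criteria_met >= 2,
                    deleterious_fraction=None,
                )
            )
    return out


_SUMSTAT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]


def read_summary_stats(path) -> list[SummaryStatRecord]:
    """Read a summary-statistics TSV (one row per variant)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        SummaryStatRecord(
            variant_id=str(row.variant_id),
            chromosome=str(row.chromosome),
            position=int(row.position),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            p=float(row.p),
            n=int(row.n),
        )
        for row in df.itertuples()
    ]


def write_summary_stats(records: list[SummaryStatRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records])[_SUMSTAT_COLUMNS].to_csv(
        path, sep="\t", index=False
    )
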