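"""Synthetic multi-cohort genotype/phenotype generation.

Cohorts are drawn from an explicit haplotype pool under Hardy–Weinberg
(two independent multinomial gamete draws per individual), so phase and
haplotype frequencies are known exactly and every downstream stage —
score statistics, gene-based tests, EM dosage estimation, haplotype
meta-analysis — can be validated against the generative truth.

The default architecture mirrors a glucose-6-phosphatase-catalytic-
subunit-2-like locus: one common regulatory variant (MAF ≈ 40%) plus
15 rare protein-altering variants (each MAF < 1%, cumulative ≈ 1.6%),
each rare allele confined to a single haplotype, with effects allowed
to run in opposing directions.  Traits follow

    Y = X beta + sum_m h_m gamma_m + b_family + eps

with a shared Normal(0, family_sd^2) intercept per sibship and
Normal(0, residual_sd^2) residuals; binary traits use a logistic link
on the same linear predictor with the intercept solved for a target
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "HaplotypePool",
    "EffectSpec",
    "FamilySpec",
    "build_g6pc2_like_pool",
    "draw_cohort",
    "draw_consortium",
]


@dataclass(frozen=True)
class HaplotypePool:
    """A finite set of haplotypes with population frequencies.

    ``haplotype_alleles`` are strings of '0'/'1' over ``variant_labels``;
    frequencies must sum to one.
    """

    variant_labels: tuple[str, ...]
    haplotype_alleles: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if abs(freq.sum() - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {freq.sum()!r}, not 1")
        if np.any(freq < 0):
            raise ValueError("negative haplotype frequency")
        m = len(self.variant_labels)
        if any(len(h) != m for h in self.haplotype_alleles):
            raise ValueError("haplotype allele strings must all have length n_variants")
        if len(set(self.haplotype_alleles)) != len(self.haplotype_alleles):
            raise ValueError("haplotypes must be distinct")
        if len(self.haplotype_alleles) != len(freq):
            raise ValueError("one frequency per haplotype required")

    @property
    def n_variants(self) -> int:
        return len(self.variant_labels)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_alleles)

    @property
    def allele_matrix(self) -> np.ndarray:
        """Haplotype × variant 0/1 matrix."""
        return np.array([[int(c) for c in h] for h in self.haplotype_alleles], dtype=float)

    def implied_maf(self) -> np.ndarray:
        """Allele frequency of the '1' allele at each variant implied by the pool."""
        return self.frequencies @ self.allele_matrix

    @property
    def reference_index(self) -> int:
        """Index of the most frequent haplotype (ties broken by order)."""
        return int(np.argmax(self.frequencies))

    def drop(self, labels: set[str] | list[str]) -> "HaplotypePool":
        """Remove haplotypes and renormalize; the reference may not be dropped."""
        labels = set(labels)
        ref = self.haplotype_alleles[self.reference_index]
        if ref in labels:
            raise ValueError("cannot drop the reference (most frequent) haplotype")
        keep = [i for i, h in enumerate(self.haplotype_alleles) if h not in labels]
        if len(keep) == len(self.haplotype_alleles):
            return self
        freq = self.frequencies[keep]
        return HaplotypePool(
            self.variant_labels,
            tuple(self.haplotype_alleles[i] for i in keep),
            freq / freq.sum(),
        )


@dataclass
class EffectSpec:
    """True generative effects for one cohort draw.

    ``haplotype_effects`` is indexed like the pool's haplotypes (trait units
    per copy); the reference haplotype's entry must be exactly 0.
    ``covariate_effects`` maps covariate name -> effect; the special name
    ``intercept`` sets the trait baseline.
    """

    haplotype_effects: np.ndarray
    covariate_effects: dict[str, float] = field(default_factory=dict)
    family_sd: float = 0.0
    residual_sd: float = 1.0
    trait_kind: str = "quantitative"
    prevalence: float = 0.15  # binary traits only: target case fraction

    def __post_init__(self) -> None:
        self.haplotype_effects = np.asarray(self.haplotype_effects, dtype=float)
        if self.family_sd < 0:
            raise ValueError("family_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.trait_kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")

    def validate_reference(self, pool: HaplotypePool) -> None:
        ref = pool.reference_index
        if self.haplotype_effects[ref] != 0.0:
            raise ValueError("effect of the reference haplotype must be exactly 0")
        if len(self.haplotype_effects) != pool.n_haplotypes:
            raise ValueError("one haplotype effect per pool haplotype required")


@dataclass
class FamilySpec:
    """Sibship structure: sizes are drawn i.i.d. from ``sibship_sizes``.

    ``sibship_sizes`` maps sibship size (>=1) to probability.  Individuals in
    a sibship share one random intercept; size-1 entries are singletons.
    """

    sibship_sizes: dict[int, float] = field(default_factory=lambda: {1: 1.0})

    def __post_init__(self) -> None:
        if not self.sibship_sizes:
            raise ValueError("sibship_sizes must be non-empty")
        if any(k < 1 for k in self.sibship_sizes):
            raise ValueError("sibship sizes must be >= 1")
        total = sum(self.sibship_sizes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sibship size probabilities must sum to 1")

    @property
    def mean_size(self) -> float:
        return sum(k * p for k, p in self.sibship_sizes.items())


UNRELATED = FamilySpec()


def build_g6pc2_like_pool(seed: int) -> HaplotypePool:
    """Haplotype pool emulating a G6PC2-like rare-variant architecture.

    16 variants: variant 0 is common (implied MAF in [0.35, 0.45]); variants
    1..15 are rare (each implied MAF < 1%, cumulative ~1.6%), and each rare
    minor allele rides on exactly one haplotype.  Haplotypes: the all-reference
    background, the common-allele haplotype, and one haplotype per rare allele.
    """
    rng = np.random.default_rng(seed)
    m = 16
    labels = tuple(f"rs9{i:05d}" for i in range(m))
    common_freq = rng.uniform(0.38, 0.42)
    # rare frequencies: lognormal spread scaled to a 1.6% cumulative MAF,
    # individually capped well below 1%
    raw = rng.lognormal(mean=0.0, sigma=0.8, size=m - 1)
    rare = 0.016 * raw / raw.sum()
    rare = np.minimum(rare, 0.008)
    haps = []
    freqs = []
    ref = "0" * m
    haps.append(ref)
    freqs.append(1.0 - common_freq - rare.sum())
    common_hap = "1" + "0" * (m - 1)
    haps.append(common_hap)
    freqs.append(common_freq)
    for j in range(1, m):
        alleles = ["0"] * m
        alleles[j] = "1"
        haps.append("".join(alleles))
        freqs.append(rare[j - 1])
    freqs = np.asarray(freqs)
    return HaplotypePool(labels, tuple(haps), freqs / freqs.sum())


def _draw_families(families: FamilySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Family id per individual; the last sibship is truncated to hit n exactly."""
    sizes = np.array(sorted(families.sibship_sizes), dtype=int)
    probs = np.array([families.sibship_sizes[k] for k in sizes])
    fam_ids = np.empty(n, dtype=int)
    i = 0
    fam = 0
    while i < n:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, n - i)
        fam_ids[i : i + k] = fam
        i += k
        fam += 1
    return fam_ids


def _solve_logistic_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(expit(eta + c)) == prevalence."""

    def f(c: float) -> float:
        return float(expit(eta + c).mean() - prevalence)

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("implied prevalence is degenerate (0 or 1)")
    return brentq(f, lo, hi, xtol=1e-10)


def draw_cohort(
    pool: HaplotypePool,
    families: FamilySpec,
    effects: EffectSpec,
    n: int,
    seed: int,
    cohort_label: str = "cohort1",
    missing_rate: float = 0.0,
):
    """Draw one cohort: genotypes, phenotypes and the generative truth.

    Returns ``(GenotypeMatrix, PhenotypeTable, truth)`` where the phenotype
    table is a pandas DataFrame with columns sample, FID, age, sex, trait
    (and ``case`` for binary traits), and ``truth`` retains phased haplotype
    indices, family intercepts and all parameters.
    """
    from glyrare.cohort import GenotypeMatrix  # container lives with the consumer

    if n < 1:
        raise ValueError("n must be >= 1")
    effects.validate_reference(pool)
    rng = np.random.default_rng(seed)

    K = pool.n_haplotypes
    hap1 = rng.choice(K, size=n, p=pool.frequencies)
    hap2 = rng.choice(K, size=n, p=pool.frequencies)
    A = pool.allele_matrix  # K x m
    dosage = A[hap1] + A[hap2]  # n x m, counts of the '1' allele

    fam_ids = _draw_families(families, n, rng)
    n_fam = fam_ids.max() + 1
    b_fam = rng.normal(0.0, effects.family_sd, size=n_fam)
    b = b_fam[fam_ids]

    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    X = {"age": age, "sex": sex}
    ce = effects.covariate_effects
    lin = np.full(n, float(ce.get("intercept", 0.0)))
    for name, beta in ce.items():
        if name == "intercept":
            continue
        if name not in X:
            raise KeyError(f"unknown covariate {name!r}")
        lin = lin + beta * X[name]
    # haplotype dosage contribution (truth-phased)
    hap_dose = np.zeros((n, K))
    np.add.at(hap_dose, (np.arange(n), hap1), 1.0)
    np.add.at(hap_dose, (np.arange(n), hap2), 1.0)
    lin = lin + hap_dose @ effects.haplotype_effects

    eps = rng.normal(0.0, effects.residual_sd, size=n)
    if effects.trait_kind == "quantitative":
        trait = lin + b + eps
        pheno = pd.DataFrame(
            {
                "sample": [f"{cohort_label}_s{i}" for i in range(n)],
                "FID": [f"{cohort_label}_f{f}" for f in fam_ids],
                "age": age,
                "sex": sex,
                "trait": trait,
            }
        )
    else:
        eta = lin + b
        c = _solve_logistic_intercept(eta, effects.prevalence)
        p = expit(eta + c)
        case = (rng.uniform(size=n) < p).astype(int)
        if case.min() == case.max():
            raise ValueError("degenerate binary trait: all cases or all controls")
        pheno = pd.DataFrame(
            {
                "sample": [f"{cohort_label}_s{i}" for i in range(n)],
                "FID": [f"{cohort_label}_f{f}" for f in fam_ids],
                "age": age,
                "sex": sex,
                "trait": case.astype(float),
                "case": case,
            }
        )

    if missing_rate > 0:
        mask = rng.uniform(size=dosage.shape) < missing_rate
        dosage = dosage.astype(float)
        dosage[mask] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": "2",
            "pos": 169_750_000 + 100 * np.arange(pool.n_variants),
            "id": list(pool.variant_labels),
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(
        dosage=np.asarray(dosage, dtype=float),
        variants=variants,
        samples=list(pheno["sample"]),
    )
    truth = {
        "cohort": cohort_label,
        "hap1": hap1,
        "hap2": hap2,
        "hap_dosage": hap_dose,
        "b": b,
        "family_ids": fam_ids,
        "pool": pool,
        "effects": effects,
        "seed": seed,
    }
    return gm, pheno, truth


def draw_consortium(pool: HaplotypePool, cohort_specs: list[dict], seed: int):
    """Draw independent cohorts, each possibly observing a reduced haplotype set.

    Each spec is a dict with keys ``name``, ``n``, ``effects`` and optionally
    ``families`` (FamilySpec), ``drop_haplotypes`` (allele strings absent from
    that cohort's pool; the reference may not be dropped) and ``missing_rate``.
    Returns ``(cohorts, manifest)`` where cohorts is a list of
    (GenotypeMatrix, PhenotypeTable, truth) and the manifest records the
    haplotypes each cohort can observe.
    """
    if not cohort_specs:
        raise ValueError("at least one cohort spec required")
    cohorts = []
    manifest = {}
    for idx, spec in enumerate(cohort_specs):
        sub = pool.drop(spec.get("drop_haplotypes", []))
        # effects must be re-indexed onto the reduced pool
        eff = spec["effects"]
        if len(eff.haplotype_effects) == pool.n_haplotypes and sub is not pool:
            keep = [i for i, h in enumerate(pool.haplotype_alleles) if h in sub.haplotype_alleles]
            eff = EffectSpec(
                haplotype_effects=eff.haplotype_effects[keep],
                covariate_effects=eff.covariate_effects,
                family_sd=eff.family_sd,
                residual_sd=eff.residual_sd,
                trait_kind=eff.trait_kind,
                prevalence=eff.prevalence,
            )
        # mix the cohort index into the stream so cohorts are independent draws
        sub_seed = int(np.random.default_rng([seed, idx]).integers(0, 2**31 - 1))
        cohort = draw_cohort(
            sub,
            spec.get("families", UNRELATED),
            eff,
            spec["n"],
            seed=sub_seed,
            cohort_label=spec.get("name", f"cohort{idx + 1}"),
            missing_rate=spec.get("missing_rate", 0.0),
        )
        cohorts.append(cohort)
        manifest[spec.get("name", f"cohort{idx + 1}")] = list(sub.haplotype_alleles)
    return cohorts, manifest
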