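"""Cohort-level null models and score statistics.

This is the "prep" stage of a two-stage score meta-analysis: every cohort
fits a covariate-only null model once, then extracts, per gene, the score
vector ``U`` (gradient of the log-likelihood at the null fit with respect to
per-variant effects) and its covariance ``V``.  The conventions follow the
score framework used for exome-chip consortium analyses:

    U_j / V_jj      estimates the per-minor-allele effect,
    1 / sqrt(V_jj)  its standard error,
    U_j / sqrt(V_jj) the score z-statistic,

which for quantitative traits means ``U = G~' R / sigma^2`` and
``V = G~' G~ / sigma^2`` with ``G~`` the genotype columns residualized on the
(whitened) covariate design and ``R`` the (whitened) null residuals.  Binary
traits use the logistic score with expected information.

All dosages are additively coded to the cohort minor allele before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from glyrare.lmm import reml_family_intercept, whiten_family

__all__ = [
    "GenotypeMatrix",
    "NullModel",
    "ScoreSet",
    "recode_to_minor",
    "freq_stats",
    "fit_null",
    "score_stats",
    "select_gene_variants",
    "PROTEIN_ALTERING",
]

# dbNSFP-style functional classes admitted to gene-based tests
PROTEIN_ALTERING = frozenset({"nonsynonymous", "splice-site", "stop"})


@dataclass
class GenotypeMatrix:
    """Sample × variant diploid dosages with per-variant metadata.

    ``dosage`` holds values in {0, 1, 2} or NaN for missing; ``variants`` is a
    DataFrame with columns chrom, pos (1-based), id, ref, alt; ``flip_log``
    records variants recoded to the minor allele.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    flip_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape must be n_samples x n_variants")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def columns(self, variant_ids: list[str]) -> np.ndarray:
        idx = self.variants.set_index("id").index
        pos = [idx.get_loc(v) for v in variant_ids]
        return self.dosage[:, pos]


@dataclass
class NullModel:
    """Covariate-only fit whose residuals feed the score statistics."""

    trait_kind: str
    beta: np.ndarray
    resid: np.ndarray
    sigma2: float
    sigma2_b: float
    lam: float  # sigma2_b / sigma2 (0 for unrelated / binary)
    fitted: np.ndarray | None  # fitted probabilities (binary only)
    n: int
    X: np.ndarray
    samples: list[str]
    family_ids: np.ndarray | None
    covariates: list[str]


@dataclass
class ScoreSet:
    """Per-gene sufficient statistics: the unit shipped to meta-analysis."""

    gene: str
    variants: pd.DataFrame  # id, ref, alt, chrom, pos, maf, mac
    U: np.ndarray
    V: np.ndarray
    n: int
    trait_kind: str
    cohort: str = "cohort"
    zero_variance: list[str] = field(default_factory=list)
    n_cases: int = 0  # binary traits only

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        m = len(self.U)
        if self.V.shape != (m, m) or len(self.variants) != m:
            raise ValueError("U, V and variant table dimensions disagree")
        if not np.allclose(self.V, self.V.T, atol=1e-10 * max(1.0, np.abs(self.V).max())):
            raise ValueError("V must be symmetric")
        if m:
            w = np.linalg.eigvalsh(self.V)
            if w.min() < -1e-8 * max(np.trace(self.V), 1e-300):
                raise ValueError("V must be positive semidefinite")


def recode_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip variants whose coded-allele frequency exceeds 0.5 to the minor allele.

    Frequency exactly 0.5 is left unflipped (deterministic).  Idempotent.
    """
    dosage = g.dosage.copy()
    variants = g.variants.copy()
    flip_log = list(g.flip_log)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        freq = np.nanmean(dosage, axis=0) / 2.0
    for j in np.flatnonzero(freq > 0.5):
        dosage[:, j] = 2.0 - dosage[:, j]
        ref, alt = variants.at[variants.index[j], "ref"], variants.at[variants.index[j], "alt"]
        variants.at[variants.index[j], "ref"] = alt
        variants.at[variants.index[j], "alt"] = ref
        flip_log.append(str(variants.at[variants.index[j], "id"]))
    return GenotypeMatrix(dosage, variants, list(g.samples), flip_log)


def freq_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, MAC and call rate for a minor-allele-coded matrix."""
    called = ~np.isnan(g.dosage)
    n_called = called.sum(axis=0)
    mac = np.nansum(g.dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_called > 0, mac / (2.0 * n_called), 0.0)
    return pd.DataFrame(
        {
            "id": g.variants["id"].to_numpy(),
            "maf": maf,
            "mac": mac,
            "call_rate": n_called / g.n_samples,
        }
    )


def _design(pheno: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(pheno))] + [pheno[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    return X


def fit_null(
    pheno: pd.DataFrame,
    covariates: list[str],
    trait_col: str = "trait",
    trait_kind: str = "quantitative",
    family_col: str | None = None,
    sample_col: str = "sample",
) -> NullModel:
    """Fit the covariate-only null model.

    Quantitative traits with a family column use a linear mixed model with one
    random intercept per family (profiled REML); unrelated quantitative traits
    use OLS.  Binary traits use logistic regression after keeping one member
    per family.  Rows with missing trait or covariates are dropped listwise.
    """
    cols = [trait_col] + covariates
    keep = pheno.dropna(subset=cols)
    if trait_kind == "binary" and family_col is not None:
        keep = keep.drop_duplicates(subset=family_col, keep="first")
    y = keep[trait_col].to_numpy(dtype=float)
    X = _design(keep, covariates)
    samples = list(keep[sample_col]) if sample_col in keep else list(map(str, keep.index))

    if trait_kind == "quantitative":
        fam = keep[family_col].to_numpy() if family_col is not None else None
        has_families = fam is not None and len(np.unique(fam)) < len(fam)
        if has_families:
            fit = reml_family_intercept(y, X, fam)
            return NullModel(
                trait_kind, fit.beta, fit.resid, fit.sigma2, fit.sigma2_b, fit.lam,
                None, fit.n, X, samples, fam, covariates,
            )
        res = sm.OLS(y, X).fit()
        sigma2 = float(res.ssr / res.df_resid)
        return NullModel(
            trait_kind, np.asarray(res.params), np.asarray(res.resid), sigma2,
            0.0, 0.0, None, len(y), X, samples, None, covariates,
        )
    if trait_kind == "binary":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("binary trait needs both classes present")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if not res.converged:
            raise RuntimeError("logistic null model did not converge")
        return NullModel(
            trait_kind, np.asarray(res.params), y - np.asarray(res.fittedvalues),
            1.0, 0.0, 0.0, np.asarray(res.fittedvalues), len(y), X, samples, None,
            covariates,
        )
    raise ValueError(f"unknown trait_kind {trait_kind!r}")


def _impute_mean(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages column-wise (all-missing columns -> 0)."""
    G = G.copy()
    miss = np.isnan(G)
    if miss.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(G, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    return G


def score_stats(
    nm: NullModel,
    g: GenotypeMatrix,
    gene_variants: list[str] | None = None,
    gene: str = "gene",
    cohort: str = "cohort",
) -> ScoreSet:
    """Score vector U and covariance V for a gene's variants at the null fit.

    Samples must align between the null model and the genotype matrix
    (the genotype rows are subset to the null model's samples, in order).
    Missing dosages are imputed to the variant's mean dosage.
    """
    variant_ids = gene_variants if gene_variants is not None else list(g.variants["id"])
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    try:
        rows = np.array([sample_pos[s] for s in nm.samples])
    except KeyError as e:
        raise ValueError(f"sample {e} missing from genotype matrix") from None
    G = _impute_mean(g.columns(variant_ids)[rows])
    freq = freq_stats(g)
    freq = freq.set_index("id").loc[variant_ids]

    zero_var = [v for v, s in zip(variant_ids, G.std(axis=0)) if s == 0]
    X = nm.X
    if nm.trait_kind == "quantitative":
        if nm.lam > 0:
            Gw = whiten_family(G, nm.family_ids, nm.lam)
            Xw = whiten_family(X, nm.family_ids, nm.lam)
            Rw = whiten_family(nm.resid, nm.family_ids, nm.lam)
        else:
            Gw, Xw, Rw = G, X, nm.resid
        # residualize genotypes on the (whitened) design
        coef, *_ = np.linalg.lstsq(Xw, Gw, rcond=None)
        Gt = Gw - Xw @ coef
        U = Gt.T @ Rw / nm.sigma2
        V = Gt.T @ Gt / nm.sigma2
    else:
        p = nm.fitted
        W = p * (1.0 - p)
        XtWX = X.T @ (X * W[:, None])
        coef = np.linalg.solve(XtWX, X.T @ (G * W[:, None]))
        Gt = G - X @ coef
        U = Gt.T @ nm.resid
        V = Gt.T @ (Gt * W[:, None])
    # zero-variance variants contribute exactly nothing
    for v in zero_var:
        j = variant_ids.index(v)
        U[j] = 0.0
        V[j, :] = 0.0
        V[:, j] = 0.0
    V = (V + V.T) / 2.0

    meta = g.variants.set_index("id").loc[variant_ids].reset_index()
    meta["maf"] = freq["maf"].to_numpy()
    meta["mac"] = freq["mac"].to_numpy()
    if nm.trait_kind == "binary":
        # minor allele count among cases: the basis of the case-side MAC
        # filter for binary-trait single-variant tests
        y = nm.resid + nm.fitted
        case_rows = rows[y > 0.5]
        meta["mac_cases"] = np.nansum(g.columns(variant_ids)[case_rows], axis=0)
        n_cases = int((y > 0.5).sum())
    return ScoreSet(
        gene=gene, variants=meta, U=U, V=V, n=nm.n, trait_kind=nm.trait_kind,
        cohort=cohort, zero_variance=zero_var,
        n_cases=n_cases if nm.trait_kind == "binary" else 0,
    )


def select_gene_variants(
    gene_variants: list[str],
    annotation: dict[str, str],
    freq: pd.DataFrame,
    trait_kind: str = "quantitative",
    maf_threshold: float = 0.01,
    cmac_threshold: int | None = None,
):
    """Apply the gene-test inclusion filters.

    Keeps protein-altering variants (nonsynonymous, splice-site, stop
    gain/loss) with MAF below ``maf_threshold`` (default 1%); the gene enters
    testing only when the cumulative MAC of kept variants reaches 20
    (quantitative) or 40 (binary).  Returns
    ``(kept_ids, passed, cmaf, cmac)``.
    """
    if cmac_threshold is None:
        cmac_threshold = 40 if trait_kind == "binary" else 20
    f = freq.set_index("id")
    kept = []
    for v in gene_variants:
        if v not in annotation:
            raise KeyError(f"variant {v!r} lacks a functional annotation")
        if annotation[v] not in PROTEIN_ALTERING:
            continue
        if 0.0 < f.at[v, "maf"] < maf_threshold:
            kept.append(v)
    cmaf = float(f.loc[kept, "maf"].sum()) if kept else 0.0
    cmac = float(f.loc[kept, "mac"].sum()) if kept else 0.0
    passed = bool(kept) and cmac >= cmac_threshold
    return kept, passed, cmaf, cmac
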