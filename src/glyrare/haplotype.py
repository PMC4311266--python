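"""Haplotype dosage estimation and family-aware haplotype meta-analysis.

A cohort's unphased genotypes over a small variant set are resolved into
expected haplotype dosages by an EM algorithm under random mating: the
E-step distributes each individual over the haplotype pairs compatible with
their genotype in proportion to current frequencies, the M-step re-estimates
frequencies from expected counts.  Individuals with at most one heterozygous
site are phase-unambiguous and get integer dosages.

Cohort-level association regresses the trait on the non-reference dosages
(ordinary least squares, or a family-random-intercept mixed model for
related samples), yielding per-haplotype effects ``gamma`` relative to the
most frequent haplotype.  Cohorts are then combined by multivariate
fixed-effects generalized least squares with selection maps, so each cohort
contributes information only for the haplotypes it observes; the global null
(all non-reference effects zero) is tested by a Wald chi-square with
``|union| - 1`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from glyrare.lmm import reml_family_intercept

__all__ = [
    "HaplotypeDosage",
    "HaplotypeFit",
    "HaplotypeMetaResult",
    "em_dosages",
    "fit_hap_model",
    "meta_hap",
    "format_hap_table",
]

_MAX_PAIR_EXPANSION = 1 << 20


@dataclass
class HaplotypeDosage:
    """EM output: haplotype labels, frequencies and expected per-sample copies."""

    labels: tuple[str, ...]  # allele strings, e.g. "0100"
    frequencies: np.ndarray
    dosage: np.ndarray  # n_samples x K expected copies
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if abs(self.frequencies.sum() - 1.0) > 1e-10:
            raise ValueError("EM frequencies must sum to 1")
        rows = self.dosage.sum(axis=1)
        if np.any(np.abs(rows - 2.0) > 1e-8):
            raise ValueError("each dosage row must sum to 2")


@dataclass
class HaplotypeFit:
    """Cohort-level haplotype effect estimates against a reference haplotype."""

    cohort: str
    reference: str
    labels: tuple[str, ...]  # non-reference haplotypes, order of gamma
    gamma: np.ndarray
    cov: np.ndarray
    n: int
    frequencies: dict[str, float]  # all haplotypes incl. reference
    beta_covariates: np.ndarray | None = None
    sigma2_b: float = 0.0
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.reference in self.labels:
            raise ValueError("reference haplotype must be excluded from gamma")
        if self.cov.shape != (len(self.gamma), len(self.gamma)):
            raise ValueError("gamma and covariance dimensions disagree")
        w = np.linalg.eigvalsh((self.cov + self.cov.T) / 2.0)
        if len(w) and w.min() < -1e-8 * max(np.trace(self.cov), 1e-300):
            raise ValueError("covariance must be positive semidefinite")


@dataclass
class HaplotypeMetaResult:
    reference: str
    labels: tuple[str, ...]  # union non-reference haplotypes
    gamma: np.ndarray
    cov: np.ndarray
    global_stat: float
    df: int
    global_p: float
    per_hap: pd.DataFrame  # label, estimate, se, z, p, cohorts
    frequencies: dict[str, float]  # pooled, incl. reference
    excluded: list[str] = field(default_factory=list)


def _enumerate_pairs(genotype: tuple[int, ...]):
    """All unordered haplotype pairs compatible with an unphased genotype.

    Genotype entries are 0/1/2 or -1 for missing (marginalized over all
    allele combinations).  Returns a list of ((h1, h2), ordered_multiplicity)
    with haplotypes as 0/1 tuples.
    """
    pairs = [((), ())]
    for gt in genotype:
        new = []
        for h1, h2 in pairs:
            if gt == 0:
                new.append((h1 + (0,), h2 + (0,)))
            elif gt == 2:
                new.append((h1 + (1,), h2 + (1,)))
            elif gt == 1:
                new.append((h1 + (0,), h2 + (1,)))
                new.append((h1 + (1,), h2 + (0,)))
            elif gt == -1:
                for a in (0, 1):
                    for b in (0, 1):
                        new.append((h1 + (a,), h2 + (b,)))
            else:
                raise ValueError(f"invalid genotype value {gt}")
            if len(new) > _MAX_PAIR_EXPANSION:
                raise ValueError("too many heterozygous/missing sites to enumerate")
        pairs = new
    # collapse ordered pairs to unordered with multiplicity
    seen: dict[tuple, int] = {}
    for h1, h2 in pairs:
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        seen[key] = seen.get(key, 0) + 1
    return list(seen.items())


def em_dosages(
    G: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune_threshold: float = 1e-6,
) -> HaplotypeDosage:
    """EM haplotype frequencies and expected dosages from unphased genotypes.

    ``G`` is n_samples x m_variants with entries 0/1/2 (minor-allele counts)
    or NaN for missing (marginalized over compatible pairs).  Initialization
    is the product of marginal allele frequencies, so the default path is
    deterministic.  Haplotypes whose converged frequency falls below
    ``prune_threshold`` are pruned and the dosages renormalized.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if m > 25:
        raise ValueError("diplotype enumeration is intractable beyond ~25 variants")
    Gi = np.where(np.isnan(G), -1, G).astype(int)

    # group identical genotype rows; EM cost scales with distinct rows only
    rows = [tuple(r) for r in Gi]
    distinct: dict[tuple, int] = {}
    counts: list[int] = []
    row_of: np.ndarray = np.empty(n, dtype=int)
    for i, r in enumerate(rows):
        if r not in distinct:
            distinct[r] = len(counts)
            counts.append(0)
        gi = distinct[r]
        counts[gi] += 1
        row_of[i] = gi
    counts_arr = np.asarray(counts, dtype=float)

    pair_lists = [_enumerate_pairs(r) for r in distinct]
    hap_index: dict[tuple, int] = {}
    for plist in pair_lists:
        for (h1, h2), _ in plist:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    haps = list(hap_index)
    K = len(haps)

    # initialization: product of marginal allele frequencies
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(G, axis=0) / 2.0
    af = np.clip(np.where(np.isnan(af), 0.5, af), 1e-6, 1 - 1e-6)
    freq = np.array(
        [np.prod(np.where(np.array(h) == 1, af, 1.0 - af)) for h in haps]
    )
    freq = freq / freq.sum()

    # flattened pair bookkeeping for vectorized E-steps
    pair_g, pair_a, pair_b, pair_mult = [], [], [], []
    for gi, plist in enumerate(pair_lists):
        for (h1, h2), mult in plist:
            pair_g.append(gi)
            pair_a.append(hap_index[h1])
            pair_b.append(hap_index[h2])
            pair_mult.append(mult)
    pair_g = np.asarray(pair_g)
    pair_a = np.asarray(pair_a)
    pair_b = np.asarray(pair_b)
    pair_mult = np.asarray(pair_mult, dtype=float)
    n_distinct = len(counts_arr)

    loglik_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        pw = pair_mult * freq[pair_a] * freq[pair_b]
        norm_g = np.bincount(pair_g, weights=pw, minlength=n_distinct)
        loglik = float(counts_arr @ np.log(np.maximum(norm_g, 1e-300)))
        if loglik < loglik_prev - 1e-9 * max(1.0, abs(loglik)):
            raise RuntimeError("EM log-likelihood decreased")  # must be monotone
        post = pw / norm_g[pair_g]
        weighted = post * counts_arr[pair_g]
        cnt = np.bincount(pair_a, weights=weighted, minlength=K)
        cnt += np.bincount(pair_b, weights=weighted, minlength=K)
        freq = cnt / (2.0 * n)
        if loglik - loglik_prev < tol and it > 1:
            converged = True
            break
        loglik_prev = loglik
    if not converged:
        raise RuntimeError(f"EM did not converge in {max_iter} iterations")

    # final posteriors and per-distinct-genotype dosage
    pw = pair_mult * freq[pair_a] * freq[pair_b]
    keep_hap = freq >= prune_threshold
    pruned_pair = keep_hap[pair_a] & keep_hap[pair_b]
    pw = np.where(pruned_pair, pw, 0.0)
    norm_g = np.bincount(pair_g, weights=pw, minlength=n_distinct)
    if np.any(norm_g <= 0):
        # pruning removed every compatible pair for some genotype; keep all haps
        keep_hap = np.ones(K, dtype=bool)
        pw = pair_mult * freq[pair_a] * freq[pair_b]
        norm_g = np.bincount(pair_g, weights=pw, minlength=n_distinct)
    post = pw / norm_g[pair_g]
    dose_g = np.zeros((n_distinct, K))
    np.add.at(dose_g, (pair_g, pair_a), post)
    np.add.at(dose_g, (pair_g, pair_b), post)

    keep_idx = np.flatnonzero(keep_hap)
    freq_kept = freq[keep_idx] / freq[keep_idx].sum()
    labels = tuple("".join(map(str, haps[i])) for i in keep_idx)
    dosage = dose_g[np.ix_(row_of, keep_idx)]
    return HaplotypeDosage(
        labels=labels, frequencies=freq_kept, dosage=dosage,
        loglik=loglik, n_iter=it, converged=True,
    )


def fit_hap_model(
    pheno: pd.DataFrame,
    covariates: list[str],
    hd: HaplotypeDosage,
    trait_col: str = "trait",
    family_col: str | None = None,
    cohort: str = "cohort",
    reference: str | None = None,
) -> HaplotypeFit:
    """Regress the trait on non-reference haplotype dosages.

    The reference defaults to the cohort's most frequent haplotype (can be
    overridden with a consortium-designated reference).  Unrelated samples
    use least squares; a family column triggers the random-intercept mixed
    model.  Collinear dosage columns are resolved by dropping the rarest
    offending haplotype (logged in ``dropped``).
    """
    K = len(hd.labels)
    if K < 2:
        raise ValueError("no haplotype variation to test (K=1)")
    if reference is None:
        reference = hd.labels[int(np.argmax(hd.frequencies))]
    if reference not in hd.labels:
        raise ValueError(f"reference haplotype {reference!r} not in EM set")

    order = [i for i, lab in enumerate(hd.labels) if lab != reference]
    labels = [hd.labels[i] for i in order]
    D = hd.dosage[:, order]
    y = pheno[trait_col].to_numpy(dtype=float)
    if len(y) != D.shape[0]:
        raise ValueError("phenotype rows must align with dosage rows")
    Xc = np.column_stack(
        [np.ones(len(y))] + [pheno[c].to_numpy(dtype=float) for c in covariates]
    )

    # drop rarest collinear dosage columns until the design has full rank
    dropped: list[str] = []
    freq_of = dict(zip(hd.labels, hd.frequencies))
    while True:
        X = np.column_stack([Xc, D])
        if np.linalg.matrix_rank(X) == X.shape[1] or not labels:
            break
        rarest = min(range(len(labels)), key=lambda i: freq_of[labels[i]])
        dropped.append(labels.pop(rarest))
        D = np.delete(D, rarest, axis=1)
    if not labels:
        raise ValueError("all haplotype dosage columns are collinear with covariates")

    p_cov = Xc.shape[1]
    fam = pheno[family_col].to_numpy() if family_col is not None else None
    has_families = fam is not None and len(np.unique(fam)) < len(fam)
    if has_families:
        fit = reml_family_intercept(y, X, fam)
        beta_full, cov_full = fit.beta, fit.cov_beta
        sigma2_b = fit.sigma2_b
    else:
        beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_full
        sigma2 = float(resid @ resid) / (len(y) - X.shape[1])
        cov_full = sigma2 * np.linalg.inv(X.T @ X)
        sigma2_b = 0.0
    gamma = beta_full[p_cov:]
    cov = cov_full[p_cov:, p_cov:]
    return HaplotypeFit(
        cohort=cohort, reference=reference, labels=tuple(labels), gamma=gamma,
        cov=(cov + cov.T) / 2.0, n=len(y),
        frequencies={lab: float(f) for lab, f in zip(hd.labels, hd.frequencies)},
        beta_covariates=beta_full[:p_cov], sigma2_b=sigma2_b, dropped=dropped,
    )


def meta_hap(fits: list[HaplotypeFit], mode: str = "gls") -> HaplotypeMetaResult:
    """Fixed-effects meta-analysis of haplotype effects across cohorts.

    With ``S_c`` the selection map from the union non-reference set to cohort
    c's haplotypes, the pooled estimate is GLS:

        gamma_meta = I^-1 sum_c S_c' Sigma_c^-1 gamma_c,
        I = sum_c S_c' Sigma_c^-1 S_c,  Cov(gamma_meta) = I^-1.

    ``mode='ivw'`` ignores cross-haplotype covariance within cohorts
    (per-coordinate inverse-variance combining), provided for sensitivity
    checks.  The global test is a Wald chi-square on all pooled effects with
    df = number of union haplotypes - 1 (the reference).
    """
    if not fits:
        raise ValueError("no cohort fits to combine")
    reference = fits[0].reference
    for f in fits:
        if f.reference != reference:
            raise ValueError("all cohorts must share the same reference haplotype")

    # pooled frequencies (2n-weighted) over all haplotypes incl. reference
    pooled_counts: dict[str, float] = {}
    total = 0.0
    for f in fits:
        for lab, fr in f.frequencies.items():
            pooled_counts[lab] = pooled_counts.get(lab, 0.0) + fr * 2 * f.n
        total += 2 * f.n
    pooled = {lab: c / total for lab, c in pooled_counts.items()}

    union = sorted(
        {lab for f in fits for lab in f.labels},
        key=lambda lab: (-pooled.get(lab, 0.0), lab),
    )
    contributing = {
        lab: [f.cohort for f in fits if lab in f.labels] for lab in union
    }
    excluded = [lab for lab in union if not contributing[lab]]
    union = [lab for lab in union if contributing[lab]]
    pos = {lab: i for i, lab in enumerate(union)}
    K = len(union)

    info = np.zeros((K, K))
    score = np.zeros(K)
    for f in fits:
        idx = np.array([pos[lab] for lab in f.labels])
        Sigma_inv = np.linalg.pinv(f.cov) if mode == "gls" else np.diag(
            1.0 / np.diag(f.cov)
        )
        if mode == "ivw":
            Sigma_inv = np.diag(np.diag(Sigma_inv))
        info[np.ix_(idx, idx)] += Sigma_inv
        score[idx] += Sigma_inv @ f.gamma

    if np.linalg.cond(info) > 1e12:
        info = info + np.eye(K) * 1e-10 * np.trace(info)
    cov = np.linalg.inv(info)
    gamma = cov @ score

    stat = float(gamma @ info @ gamma)
    df = K  # = |union incl. reference| - 1
    global_p = float(chi2.sf(stat, df))
    se = np.sqrt(np.diag(cov))
    z = gamma / se
    per_hap = pd.DataFrame(
        {
            "label": union,
            "frequency": [pooled.get(lab, 0.0) for lab in union],
            "estimate": gamma,
            "se": se,
            "z": z,
            "p": 2.0 * norm.sf(np.abs(z)),
            "cohorts": [",".join(contributing[lab]) for lab in union],
        }
    )
    return HaplotypeMetaResult(
        reference=reference, labels=tuple(union), gamma=gamma, cov=cov,
        global_stat=stat, df=df, global_p=global_p, per_hap=per_hap,
        frequencies=pooled, excluded=excluded,
    )


def format_hap_table(res: HaplotypeMetaResult) -> pd.DataFrame:
    """Report table: haplotypes by decreasing pooled frequency.

    The reference row shows effect 0 with a blank p; the global test p is
    attached as DataFrame attrs (``global_p``, ``global_df``).
    """
    rows = [
        {
            "haplotype": res.reference,
            "frequency": res.frequencies.get(res.reference, 0.0),
            "estimate": 0.0,
            "se": np.nan,
            "p": np.nan,
        }
    ]
    for _, r in res.per_hap.iterrows():
        rows.append(
            {
                "haplotype": r["label"],
                "frequency": r["frequency"],
                "estimate": r["estimate"],
                "se": r["se"],
                "p": r["p"],
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "frequency", ascending=False, kind="stable"
    ).reset_index(drop=True)
    table.attrs["global_p"] = res.global_p
    table.attrs["global_df"] = res.df
    table.attrs["reference"] = res.reference
    return table
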