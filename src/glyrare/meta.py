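"""Meta-analysis of cohort score statistics.

Cohort ``ScoreSet``s are combined by summing score vectors and covariances
over the union variant list (variants a cohort never saw contribute zeros),
after reconciling allele coding.  On the combined statistics this module
provides single-variant tests, the SKAT variance-component test with
Beta(1,25)-density ("Wu") weights, the Madsen–Browning weighted-sum burden
test, conditional analysis by covariance projection, the leave-one-variant-
out SKAT scan, exact binomial direction-consistency tests and Bonferroni
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm

from glyrare.cohort import ScoreSet
from glyrare.quadform import quadform_pvalue

__all__ = [
    "MetaScoreSet",
    "GeneTestResult",
    "combine_scores",
    "single_variant_meta",
    "skat",
    "wst_burden",
    "conditional_adjust",
    "loo_skat_scan",
    "direction_consistency",
    "bonferroni_threshold",
    "wu_weights",
    "madsen_browning_weights",
]


@dataclass
class MetaScoreSet:
    """Combined scores over the union variant list of the contributing cohorts."""

    gene: str
    variants: pd.DataFrame  # id, ref, alt, chrom, pos, maf (pooled), mac (pooled)
    U: np.ndarray
    V: np.ndarray
    n: int
    trait_kind: str
    cohorts: list[str] = field(default_factory=list)
    conditioning: list[str] = field(default_factory=list)

    @property
    def maf(self) -> np.ndarray:
        return self.variants["maf"].to_numpy(dtype=float)

    def subset(self, variant_ids: list[str]) -> "MetaScoreSet":
        order = {v: i for i, v in enumerate(self.variants["id"])}
        idx = np.array([order[v] for v in variant_ids])
        return MetaScoreSet(
            gene=self.gene,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            U=self.U[idx],
            V=self.V[np.ix_(idx, idx)],
            n=self.n,
            trait_kind=self.trait_kind,
            cohorts=list(self.cohorts),
            conditioning=list(self.conditioning),
        )


@dataclass
class GeneTestResult:
    gene: str
    test: str  # "SKAT" | "WST"
    statistic: float
    p: float
    cmaf: float
    n_variants: int
    conditioning: list[str] = field(default_factory=list)
    method: str = ""  # p-value machinery that produced p
    direction: int = 0  # burden only: sign of the weighted score


def _variant_key(row) -> tuple:
    return (row["id"], row["chrom"], row["pos"])


def combine_scores(sets: list[ScoreSet]) -> MetaScoreSet:
    """Sum cohort scores element-wise over the union variant list.

    Cohorts coding the opposite allele are reconciled by flipping the sign of
    ``U`` and the corresponding rows/columns of ``V`` and mirroring the MAF;
    a cohort whose ref/alt pair cannot be reconciled raises.  Pooled MAF is
    the allele-count-weighted average over contributing cohorts.
    """
    if not sets:
        raise ValueError("no score sets to combine")
    gene = sets[0].gene
    kind = sets[0].trait_kind
    for s in sets:
        if s.gene != gene:
            raise ValueError("all score sets must describe the same gene")
        if s.trait_kind != kind:
            raise ValueError("cannot combine different trait kinds")

    # union variant list in first-seen order, keyed by id+position
    union: dict[tuple, dict] = {}
    for s in sets:
        for _, row in s.variants.iterrows():
            key = _variant_key(row)
            if key not in union:
                union[key] = {
                    "id": row["id"], "chrom": row["chrom"], "pos": row["pos"],
                    "ref": row["ref"], "alt": row["alt"],
                }
    keys = list(union)
    index = {k: i for i, k in enumerate(keys)}
    m = len(keys)

    U = np.zeros(m)
    V = np.zeros((m, m))
    ac = np.zeros(m)  # pooled minor allele count
    an = np.zeros(m)  # pooled allele number (2 * n_called)
    ac_cases = np.zeros(m)  # pooled minor allele count among cases (binary)
    n_total = 0
    n_cases_total = 0
    cohorts = []
    for s in sets:
        n_total += s.n
        cohorts.append(s.cohort)
        idx = []
        sign = []
        for _, row in s.variants.iterrows():
            key = _variant_key(row)
            ref_alleles = (union[key]["ref"], union[key]["alt"])
            if (row["ref"], row["alt"]) == ref_alleles:
                sgn = 1.0
            elif (row["alt"], row["ref"]) == ref_alleles:
                sgn = -1.0
            else:
                raise ValueError(
                    f"irreconcilable alleles for {row['id']}: "
                    f"{(row['ref'], row['alt'])} vs {ref_alleles}"
                )
            idx.append(index[key])
            sign.append(sgn)
        idx = np.array(idx)
        sign = np.array(sign)
        U[idx] += sign * s.U
        V[np.ix_(idx, idx)] += np.outer(sign, sign) * s.V
        maf_c = s.variants["maf"].to_numpy(dtype=float)
        maf_c = np.where(sign > 0, maf_c, 1.0 - maf_c)
        ac[idx] += maf_c * 2 * s.n
        an[idx] += 2 * s.n
        if kind == "binary" and "mac_cases" in s.variants:
            mc = s.variants["mac_cases"].to_numpy(dtype=float)
            mc = np.where(sign > 0, mc, 2 * s.n_cases - mc)
            ac_cases[idx] += mc
            n_cases_total += s.n_cases

    variants = pd.DataFrame([union[k] for k in keys])
    with np.errstate(invalid="ignore", divide="ignore"):
        variants["maf"] = np.where(an > 0, ac / an, 0.0)
    variants["mac"] = ac
    if kind == "binary":
        variants["mac_cases"] = ac_cases
    return MetaScoreSet(
        gene=gene, variants=variants, U=U, V=(V + V.T) / 2.0, n=n_total,
        trait_kind=kind, cohorts=cohorts,
    )


def single_variant_meta(
    ms: MetaScoreSet, variant_id: str, mac_threshold: float = 20.0
) -> dict:
    """Effect estimate, SE and two-sided normal p for one variant.

    Variants below the pooled-MAC threshold (20, counted among cases for
    binary traits upstream) or with zero variance are flagged as filtered.
    """
    order = {v: i for i, v in enumerate(ms.variants["id"])}
    j = order[variant_id]
    vjj = ms.V[j, j]
    if ms.trait_kind == "binary" and "mac_cases" in ms.variants:
        mac = float(ms.variants["mac_cases"].iloc[j])  # MAC counted in cases
    else:
        mac = float(ms.variants["mac"].iloc[j])
    if vjj <= 0 or mac < mac_threshold:
        return {"id": variant_id, "filtered": True, "beta": np.nan, "se": np.nan,
                "z": np.nan, "p": np.nan, "mac": mac}
    beta = ms.U[j] / vjj
    se = 1.0 / np.sqrt(vjj)
    z = ms.U[j] / np.sqrt(vjj)
    p = 1.0 if ms.U[j] == 0 else 2.0 * norm.sf(abs(z))
    return {"id": variant_id, "filtered": False, "beta": float(beta),
            "se": float(se), "z": float(z), "p": float(p), "mac": mac}


def wu_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1,25)-density weights on MAF (the SKAT default)."""
    return beta_dist.pdf(np.asarray(maf, dtype=float), a, b)


def madsen_browning_weights(maf: np.ndarray, n: int) -> np.ndarray:
    """Inverse binomial-SD weights 1/sqrt(n p (1-p)) on pooled MAF.

    Monomorphic variants (p in {0, 1}) carry no information and get weight 0.
    """
    p = np.asarray(maf, dtype=float)
    ok = (p > 0) & (p < 1)
    w = np.zeros_like(p)
    w[ok] = 1.0 / np.sqrt(n * p[ok] * (1.0 - p[ok]))
    return w


def skat(ms: MetaScoreSet, weights: np.ndarray | None = None) -> GeneTestResult:
    """SKAT: Q = sum_j w_j^2 U_j^2 against the eigenvalues of W V W."""
    if weights is None:
        weights = wu_weights(ms.maf)
    w = np.asarray(weights, dtype=float)
    if np.allclose(ms.V, 0.0):
        raise ValueError("all-zero covariance; SKAT undefined")
    Q = float(np.sum((w * ms.U) ** 2))
    WVW = (w[:, None] * ms.V) * w[None, :]
    lam = np.linalg.eigvalsh(WVW)
    p, method = quadform_pvalue(Q, lam)
    return GeneTestResult(
        gene=ms.gene, test="SKAT", statistic=Q, p=p,
        cmaf=float(ms.maf.sum()), n_variants=len(ms.U),
        conditioning=list(ms.conditioning), method=method,
    )


def wst_burden(ms: MetaScoreSet, weights: np.ndarray | None = None) -> GeneTestResult:
    """Weighted-sum burden test with Madsen–Browning weights.

    S = w'U with variance w'Vw; two-sided normal p; the sign of S gives the
    aggregate direction of effect.
    """
    if weights is None:
        weights = madsen_browning_weights(ms.maf, ms.n)
    w = np.asarray(weights, dtype=float)
    if np.allclose(ms.V, 0.0):
        raise ValueError("all-zero covariance; burden test undefined")
    S = float(w @ ms.U)
    var = float(w @ ms.V @ w)
    if var <= 0:
        raise ValueError("zero burden variance")
    z = S / np.sqrt(var)
    p = 1.0 if S == 0 else 2.0 * norm.sf(abs(z))
    return GeneTestResult(
        gene=ms.gene, test="WST", statistic=z, p=float(p),
        cmaf=float(ms.maf.sum()), n_variants=len(ms.U),
        conditioning=list(ms.conditioning), method="normal",
        direction=int(np.sign(S)),
    )


def conditional_adjust(ms: MetaScoreSet, conditioning: list[str]) -> MetaScoreSet:
    """Project the conditioning variants' signal out of the scores.

    U* = U_g - V_gc V_cc^-1 U_c and V* = V_gg - V_gc V_cc^-1 V_cg, the score
    analogue of adding the conditioning genotypes to the covariate design.
    Near-singular V_cc is ridge-stabilized at 1e-8 of its trace.
    """
    if not conditioning:
        return ms
    ids = list(ms.variants["id"])
    missing = [c for c in conditioning if c not in ids]
    if missing:
        raise ValueError(f"conditioning variants absent from score set: {missing}")
    c_idx = np.array([ids.index(c) for c in conditioning])
    g_idx = np.array([i for i in range(len(ids)) if i not in set(c_idx)])
    Vcc = ms.V[np.ix_(c_idx, c_idx)]
    if np.linalg.cond(Vcc) > 1e12:
        Vcc = Vcc + np.eye(len(c_idx)) * 1e-8 * np.trace(Vcc)
    Vgc = ms.V[np.ix_(g_idx, c_idx)]
    solve = np.linalg.solve(Vcc, np.column_stack([ms.U[c_idx], Vgc.T]))
    U_adj = ms.U[g_idx] - Vgc @ solve[:, 0]
    V_adj = ms.V[np.ix_(g_idx, g_idx)] - Vgc @ solve[:, 1:]
    return MetaScoreSet(
        gene=ms.gene,
        variants=ms.variants.iloc[g_idx].reset_index(drop=True),
        U=U_adj, V=(V_adj + V_adj.T) / 2.0, n=ms.n, trait_kind=ms.trait_kind,
        cohorts=list(ms.cohorts),
        conditioning=list(ms.conditioning) + list(conditioning),
    )


def loo_skat_scan(ms: MetaScoreSet) -> pd.DataFrame:
    """Leave-one-variant-out SKAT scan over the gene's variants.

    One row per removed variant (ordered by position), with the SKAT
    statistic and p recomputed on the remaining set, weights recomputed on
    the remaining MAFs.
    """
    if len(ms.U) < 2:
        raise ValueError("leave-one-out scan needs at least 2 variants")
    rows = []
    ids = list(ms.variants["id"])
    for v in ids:
        rest = [x for x in ids if x != v]
        sub = ms.subset(rest)
        res = skat(sub)
        rows.append({"removed": v,
                     "pos": int(ms.variants.set_index("id").at[v, "pos"]),
                     "Q": res.statistic, "p": res.p})
    return (
        pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    )


def direction_consistency(observed_signs, reference_signs) -> tuple[int, int, float]:
    """Exact one-sided binomial test of direction agreement.

    Returns (k, n, p) with k the number of sign agreements among n and
    p = P(X >= k | n, 1/2).
    """
    obs = np.asarray(observed_signs, dtype=int)
    ref = np.asarray(reference_signs, dtype=int)
    if obs.shape != ref.shape:
        raise ValueError("sign vectors must have equal length")
    if np.any(obs == 0) or np.any(ref == 0):
        raise ValueError("zero signs are not allowed")
    n = len(obs)
    k = int(np.sum(obs == ref))
    p = float(binom.sf(k - 1, n, 0.5))
    return k, n, p


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
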