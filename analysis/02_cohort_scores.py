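"""Cohort stage: read each simulated cohort back from disk, recode dosages to
the minor allele, fit the family-intercept null model and extract per-gene
score statistics (U, V).  Writes one interchange JSON per cohort under
results/scores/ — the only thing the meta stage ever sees.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from glyrare import io as gio
from glyrare.cohort import fit_null, freq_stats, recode_to_minor, score_stats


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results" / "scores"
    out.mkdir(parents=True, exist_ok=True)
    for cdir in sorted(data.glob("cohort*")):
        gm = recode_to_minor(gio.read_vcf_minimal(cdir / "genotypes.vcf"))
        ph = gio.read_phenotypes(cdir / "phenotypes.tsv")
        nm = fit_null(ph, ["age", "sex"], family_col="FID")
        ss = score_stats(nm, gm, gene="G6PC2_like", cohort=cdir.name)
        gio.write_scoreset(ss, out / f"{cdir.name}.scores.json")
        fs = freq_stats(gm)
        n_rare = int(((fs["maf"] > 0) & (fs["maf"] < 0.01)).sum())
        print(
            f"{cdir.name}: n={nm.n}, sigma2={nm.sigma2:.3f}, "
            f"sigma2_b={nm.sigma2_b:.3f}, {n_rare} polymorphic rare variants"
        )
    print(f"score sets -> {out}")


if __name__ == "__main__":
    main()
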