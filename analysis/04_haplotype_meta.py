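"""Haplotype stage: estimate EM posterior haplotype dosages per cohort, fit the
cohort-level haplotype regression (family random intercept, most frequent
haplotype as reference) and combine the per-cohort effect vectors by
multivariate fixed-effects GLS.  Writes the cohort fit JSONs and the final
haplotype report table (ordered by decreasing pooled frequency, global test
in the header attributes).
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from glyrare import io as gio
from glyrare.cohort import recode_to_minor
from glyrare.haplotype import em_dosages, fit_hap_model, format_hap_table, meta_hap


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results" / "tables"
    out.mkdir(parents=True, exist_ok=True)
    fits = []
    reference = None
    for cdir in sorted(data.glob("cohort*")):
        gm = recode_to_minor(gio.read_vcf_minimal(cdir / "genotypes.vcf"))
        ph = gio.read_phenotypes(cdir / "phenotypes.tsv")
        hd = em_dosages(gm.dosage, max_iter=10_000)
        if reference is None:
            reference = "0" * gm.n_variants  # consortium reference haplotype
        hf = fit_hap_model(
            ph, ["age", "sex"], hd, family_col="FID", cohort=cdir.name,
            reference=reference,
        )
        gio.write_hapfit(hf, ROOT / "results" / "scores" / f"{cdir.name}.hapfit.json")
        fits.append(hf)
        print(f"{cdir.name}: {len(hf.labels)} non-reference haplotypes, "
              f"EM iters={hd.n_iter}")
    res = meta_hap(fits)
    table = format_hap_table(res)
    table.to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    print(f"global haplotype test: chi2={res.global_stat:.1f}, df={res.df}, "
          f"p={res.global_p:.3g}")
    top = res.per_hap.nsmallest(3, "p")[["label", "estimate", "se", "p"]]
    print("strongest individual haplotypes vs reference:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
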