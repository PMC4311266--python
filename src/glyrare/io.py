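"""File formats: minimal VCF 4.2, delimited tables, JSON interchange.

The cohort and meta stages exchange only summary containers — ``ScoreSet``
and ``HaplotypeFit`` — serialized as JSON with full-precision decimal floats
so that write/read round-trips are exact to the last bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glyrare.cohort import GenotypeMatrix, ScoreSet
from glyrare.haplotype import HaplotypeFit

__all__ = [
    "read_vcf_minimal",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "write_scoreset",
    "read_scoreset",
    "write_hapfit",
    "read_hapfit",
]

_GT_DOSAGE = {"0": 0.0, "1": 1.0, ".": np.nan}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with unphased GT fields."""
    path = Path(path)
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, (_, v) in enumerate(g.variants.iterrows()):
            gts = [
                "./." if np.isnan(d) else code[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf_minimal(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic diploid VCF into a dosage matrix (ALT-allele counts).

    Multiallelic records are rejected with their position; ``./.`` becomes
    missing; phased separators are accepted, phase is ignored at this layer.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = ALT dosage, 3 = missing
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split before loading"
            )
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        # gt_types: 0=hom-ref 1=het 2=hom-alt 3=unknown
        gt = rec.gt_types.astype(float)
        gt[gt == 3.0] = np.nan
        gt[gt == 2.0] = 2.0
        dosages.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"no records in {path}")
    dosage = np.column_stack(dosages)
    return GenotypeMatrix(dosage=dosage, variants=pd.DataFrame(rows), samples=samples)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotation(path: str | Path) -> dict[str, str]:
    """Variant -> functional class mapping from a two-column TSV (id, class)."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "class"}.issubset(df.columns):
        raise ValueError("annotation table needs 'id' and 'class' columns")
    return dict(zip(df["id"].astype(str), df["class"].astype(str)))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_scoreset(s: ScoreSet, path: str | Path) -> None:
    payload = {
        "container": "scoreset",
        "gene": s.gene,
        "cohort": s.cohort,
        "trait_kind": s.trait_kind,
        "n": s.n,
        "variants": s.variants.to_dict(orient="list"),
        "U": s.U,
        "V": s.V.reshape(-1),  # row-major
        "zero_variance": s.zero_variance,
        "n_cases": s.n_cases,
    }
    Path(path).write_text(json.dumps(payload, default=_jsonify, indent=1))


def read_scoreset(path: str | Path) -> ScoreSet:
    d = json.loads(Path(path).read_text())
    if d.get("container") != "scoreset":
        raise ValueError(f"{path} is not a score-set container")
    m = len(d["U"])
    return ScoreSet(
        gene=d["gene"],
        variants=pd.DataFrame(d["variants"]),
        U=np.asarray(d["U"], dtype=float),
        V=np.asarray(d["V"], dtype=float).reshape(m, m),
        n=int(d["n"]),
        trait_kind=d["trait_kind"],
        cohort=d["cohort"],
        zero_variance=list(d.get("zero_variance", [])),
        n_cases=int(d.get("n_cases", 0)),
    )


def write_hapfit(f: HaplotypeFit, path: str | Path) -> None:
    payload = {
        "container": "hapfit",
        "cohort": f.cohort,
        "reference": f.reference,
        "labels": list(f.labels),
        "gamma": f.gamma,
        "cov": f.cov.reshape(-1),
        "n": f.n,
        "frequencies": f.frequencies,
        "beta_covariates": f.beta_covariates,
        "sigma2_b": f.sigma2_b,
        "dropped": f.dropped,
    }
    Path(path).write_text(json.dumps(payload, default=_jsonify, indent=1))


def read_hapfit(path: str | Path) -> HaplotypeFit:
    d = json.loads(Path(path).read_text())
    if d.get("container") != "hapfit":
        raise ValueError(f"{path} is not a haplotype-fit container")
    k = len(d["gamma"])
    return HaplotypeFit(
        cohort=d["cohort"],
        reference=d["reference"],
        labels=tuple(d["labels"]),
        gamma=np.asarray(d["gamma"], dtype=float),
        cov=np.asarray(d["cov"], dtype=float).reshape(k, k),
        n=int(d["n"]),
        frequencies={k_: float(v) for k_, v in d["frequencies"].items()},
        beta_covariates=(
            np.asarray(d["beta_covariates"], dtype=float)
            if d.get("beta_covariates") is not None
            else None
        ),
        sigma2_b=float(d.get("sigma2_b", 0.0)),
        dropped=list(d.get("dropped", [])),
    )
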