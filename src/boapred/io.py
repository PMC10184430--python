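"""File formats: phased VCF, origins TSV, pedigree/phenotype CSV, fits.

Genotypes travel as phased VCF (GT with the '|' separator; unphased,
non-diploid or non-biallelic records are rejected with their position).
Breed origins are a TSV matrix with one row per (animal, haplotype) and
one column per marker; integer codes, -1 meaning unassigned.  Pedigree
and phenotypes are plain CSV.  Fitted models are serialized as a .npz
array container with a JSON metadata entry.  All writers round-trip
losslessly through the matching readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .mcmc import McmcSettings, PosteriorFit
from .simulate import UNASSIGNED, BreedOrigins, PhasedGenotypes

_VCF_HEADER = """##fileformat=VCFv4.2
##source=boapred
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_phased_vcf(path: str | Path, genotypes: PhasedGenotypes) -> None:
    """Write phased genotypes as a minimal single-contig VCF."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.animal_ids)
            + "\n"
        )
        al = genotypes.alleles
        for j, mid in enumerate(genotypes.marker_ids):
            gts = "\t".join(f"{al[i, 0, j]}|{al[i, 1, j]}" for i in range(al.shape[0]))
            fh.write(f"1\t{j + 1}\t{mid}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a phased, diploid, biallelic VCF into a haplotype array.

    Raises with the offending record's position when a genotype is
    unphased, the ploidy is not 2 or the record is not biallelic.
    """
    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {where}")
        gts = var.genotypes  # [a0, a1, phased] per sample
        block = np.empty((len(animal_ids), 2), dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(
                    f"ploidy != 2 at {where}, sample {animal_ids[i]}"
                )
            a0, a1, phased = gt
            if not phased:
                raise ValueError(
                    f"unphased genotype at {where}, sample {animal_ids[i]}"
                )
            if a0 not in (0, 1) or a1 not in (0, 1):
                raise ValueError(f"missing or bad allele at {where}, sample {animal_ids[i]}")
            block[i, 0], block[i, 1] = a0, a1
        rows.append(block)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"m{len(marker_ids):05d}")
    alleles = np.stack(rows, axis=2) if rows else np.empty((len(animal_ids), 2, 0), np.uint8)
    return PhasedGenotypes(alleles, animal_ids, marker_ids)


def write_origins_tsv(
    path: str | Path, origins: BreedOrigins, animal_ids: list[str], marker_ids: list[str]
) -> None:
    """Origins as TSV: rows animal_hap0/animal_hap1, columns markers."""
    n, _, m = origins.origins.shape
    index = [f"{a}_hap{h}" for a in animal_ids for h in range(2)]
    flat = origins.origins.reshape(n * 2, m)
    pd.DataFrame(flat, index=index, columns=marker_ids).to_csv(path, sep="\t", index_label="haplotype")


def read_origins_tsv(path: str | Path, n_breeds: int) -> BreedOrigins:
    """Read the origins TSV; codes outside {-1, 0..n_breeds-1} are rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=np.int64)
    bad = (vals < UNASSIGNED) | (vals >= n_breeds)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"origin code {vals[r, c]} outside {{-1, 0..{n_breeds - 1}}} "
            f"at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if vals.shape[0] % 2:
        raise ValueError("origins TSV must have two rows per animal")
    n = vals.shape[0] // 2
    return BreedOrigins(vals.reshape(n, 2, -1).astype(np.int8), n_breeds)


def write_tables(out_dir: str | Path, pedigree: pd.DataFrame, phenotypes: pd.DataFrame) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree.to_csv(out / "pedigree.csv", index=False)
    phenotypes.to_csv(out / "phenotypes.csv", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, keep_default_na=False)
    required = {"animal", "sire", "dam", "birth_year", "breed_label", "is_purebred"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree is missing columns: {sorted(missing)}")
    if ped["is_purebred"].dtype == object:
        ped["is_purebred"] = ped["is_purebred"].map({"True": True, "False": False})
    ped["birth_year"] = pd.to_numeric(ped["birth_year"])
    return ped


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    phe = pd.read_csv(path)
    if not {"animal", "adjusted_phenotype"} <= set(phe.columns):
        raise ValueError("phenotypes must have columns animal, adjusted_phenotype")
    return phe


def save_fit(path: str | Path, fit: PosteriorFit) -> None:
    """Serialize a posterior fit as .npz arrays plus a JSON metadata entry."""
    meta = {
        "mu_hat": fit.mu_hat,
        "breeds": list(fit.breeds) if fit.breeds is not None else None,
        "settings": dataclasses.asdict(fit.settings),
        "variance_keys": list(fit.variance_samples),
        "has_b": fit.b_hat is not None,
        "has_freqs": fit.centering_freqs is not None,
        "n_retained": fit.diagnostics.get("n_retained"),
    }
    arrays = {"u_hat": fit.u_hat}
    if fit.b_hat is not None:
        arrays["b_hat"] = fit.b_hat
    if fit.centering_freqs is not None:
        arrays["centering_freqs"] = fit.centering_freqs
    for k, v in fit.variance_samples.items():
        arrays[f"vs_{k}"] = v
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_fit(path: str | Path) -> PosteriorFit:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        samples = {k: data[f"vs_{k}"] for k in meta["variance_keys"]}
        return PosteriorFit(
            u_hat=data["u_hat"],
            b_hat=data["b_hat"] if meta["has_b"] else None,
            mu_hat=meta["mu_hat"],
            breeds=tuple(meta["breeds"]) if meta["breeds"] is not None else None,
            variance_samples=samples,
            settings=McmcSettings(**meta["settings"]),
            diagnostics={"n_retained": meta["n_retained"]},
            centering_freqs=data["centering_freqs"] if meta["has_freqs"] else None,
        )
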