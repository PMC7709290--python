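"""File readers/writers and pipeline configuration.

Canonical interchange is headered CSV: a 3-column pedigree (animal, sire,
dam; unknown parent "0" or empty), a phenotype table (animal + trait and
fixed-effect columns), and a dosage matrix (animal column + one column
per SNP, missing coded "NA") with a separate SNP map (snp, chrom, pos).
PLINK .raw/.bim is accepted as an alternative genotype dialect. All
matrices are exported with id labels; nothing is coupled positionally
across files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import RelationshipMatrix, ValidationError
from .pedigree import Pedigree, parse_pedigree
from .qc import GenotypePanel
from .reml import LinkageError

MISSING_TOKENS = ("NA", "", "NaN", "nan", ".")


# ---------------------------------------------------------------- readers

def read_pedigree(path, unknown_token: str = "0") -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: pedigree needs 3 columns (animal, sire, dam)")
    triples = list(df.iloc[:, :3].itertuples(index=False, name=None))
    return parse_pedigree(triples, unknown_tokens=(unknown_token, ""))


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "animal" not in df.columns:
        raise ValidationError(f"{path}: phenotype table needs an 'animal' column")
    df["animal"] = df["animal"].astype(str)
    return df


def read_genotypes(path, map_path, missing_token: str = "NA") -> GenotypePanel:
    """Dosage matrix CSV (animal + SNP columns) plus a SNP map CSV."""
    df = pd.read_csv(path, na_values=[missing_token, *MISSING_TOKENS])
    if "animal" not in df.columns:
        raise ValidationError(f"{path}: genotype matrix needs an 'animal' column")
    animals = df["animal"].astype(str).tolist()
    snp_ids = [c for c in df.columns if c != "animal"]
    dosages = df[snp_ids].to_numpy(dtype=float)
    snp_map = read_snp_map(map_path)
    order = {s: i for i, s in enumerate(snp_map["snp"])}
    missing_snps = [s for s in snp_ids if s not in order]
    if missing_snps:
        raise ValidationError(f"{map_path}: SNP {missing_snps[0]!r} not in map")
    snp_map = snp_map.set_index("snp").loc[snp_ids].reset_index()
    return GenotypePanel(dosages, tuple(animals), snp_map)


def read_snp_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, dtype={"snp": str, "chrom": str})
    need = {"snp", "chrom", "pos"}
    if not need.issubset(m.columns):
        raise ValidationError(f"{path}: SNP map needs columns {sorted(need)}")
    m["pos"] = pd.to_numeric(m["pos"], errors="coerce")
    return m


def read_plink_raw(raw_path, bim_path) -> GenotypePanel:
    """PLINK --recode A (.raw) dosage export plus the .bim map."""
    raw = pd.read_csv(raw_path, sep=r"\s+", na_values=list(MISSING_TOKENS))
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if not set(meta).issubset(raw.columns):
        raise ValidationError(f"{raw_path}: not a PLINK .raw file (missing header)")
    snp_cols = [c for c in raw.columns if c not in meta]
    animals = raw["IID"].astype(str).tolist()
    dosages = raw[snp_cols].to_numpy(dtype=float)
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str},
    )
    # .raw columns are "<snp>_<counted allele>"
    base = {c: c.rsplit("_", 1)[0] for c in snp_cols}
    bim_idx = bim.set_index("snp")
    rows = []
    for c in snp_cols:
        s = base[c]
        if s not in bim_idx.index:
            raise ValidationError(f"{bim_path}: SNP {s!r} not in .bim")
        rows.append({"snp": s, "chrom": bim_idx.loc[s, "chrom"],
                     "pos": float(bim_idx.loc[s, "pos"])})
    return GenotypePanel(dosages, tuple(animals), pd.DataFrame(rows))


# ---------------------------------------------------------------- writers

def write_pedigree(ped: Pedigree, path, unknown_token: str = "0") -> None:
    rows = []
    for a in ped.ids:
        s, d = ped.parents_of(a)
        rows.append({"animal": a, "sire": s or unknown_token, "dam": d or unknown_token})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_genotypes(panel: GenotypePanel, path, map_path,
                    missing_token: str = "NA") -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.snp_map["snp"].tolist())
    df.insert(0, "animal", list(panel.animal_ids))
    df.to_csv(path, index=False, na_rep=missing_token)
    panel.snp_map.to_csv(map_path, index=False)


def write_matrix_csv(mat: RelationshipMatrix, path) -> None:
    """Dense labelled CSV; intended for small matrices."""
    pd.DataFrame(mat.dense(), index=list(mat.ids), columns=list(mat.ids)).to_csv(path)


def write_matrix_triplets(mat: RelationshipMatrix, path, tol: float = 0.0) -> None:
    dense = mat.dense()
    ii, jj = np.nonzero(np.abs(dense) > tol) if tol else np.nonzero(np.ones_like(dense))
    keep = ii <= jj
    pd.DataFrame(
        {"id_i": [mat.ids[i] for i in ii[keep]],
         "id_j": [mat.ids[j] for j in jj[keep]],
         "value": dense[ii[keep], jj[keep]]}
    ).to_csv(path, index=False)


def write_ebv(results, path) -> None:
    frames = []
    for res in results:
        frames.append(pd.DataFrame({"animal": res.ebv.index, "model": res.model,
                                    "ebv": res.ebv.to_numpy()}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ------------------------------------------------------------ configuration

@dataclass
class PipelineConfig:
    """Flat config for the CLI; YAML round-trips losslessly."""

    pedigree: str = "pedigree.csv"
    phenotypes: str = "phenotypes.csv"
    genotypes: str = "genotypes.csv"
    snp_map: str = "snp_map.csv"
    out_dir: str = "out"
    unknown_parent: str = "0"
    traits: tuple[str, ...] = ()
    factors: tuple[str, ...] = ("cg", "birth_place")
    covariates: tuple[str, ...] = ("age",)
    max_missing_rate: float = 0.10
    call_rate_min: float = 0.98
    maf_min: float = 0.01
    het_dev_max: float = 0.15
    blend_w_g: float = 0.95
    reml_tol: float = 1e-8
    reml_max_iter: int = 100
    cv_k: int = 5
    cv_seed: int = 0
    models: tuple[str, ...] = ("PBLUP_G", "PBLUP", "GBLUP", "ssGBLUP")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        fields_ = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - fields_
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def read_inputs(cfg: PipelineConfig):
    """Load and align pedigree, phenotypes and genotypes.

    Every phenotyped animal must be in the pedigree (hard error);
    genotyped animals missing from the pedigree are a hard error too.
    Returns a dict bundle with cross-file id diagnostics.
    """
    ped = read_pedigree(cfg.pedigree, cfg.unknown_parent)
    phen = read_phenotypes(cfg.phenotypes)
    panel = read_genotypes(cfg.genotypes, cfg.snp_map)
    ped_ids = set(ped.ids)
    orphans = [a for a in phen["animal"] if a not in ped_ids]
    if orphans:
        raise LinkageError(
            f"phenotyped animal {orphans[0]!r} is not in the pedigree "
            f"({len(orphans)} such animals)"
        )
    missing_geno = [a for a in panel.animal_ids if a not in ped_ids]
    if missing_geno:
        raise LinkageError(
            f"genotyped animal {missing_geno[0]!r} is not in the pedigree"
        )
    diagnostics = {
        "n_pedigree": ped.n,
        "n_phenotyped": phen["animal"].nunique(),
        "n_genotyped": panel.n_animals,
        "n_genotyped_with_phenotype": int(
            pd.Series(list(panel.animal_ids)).isin(set(phen["animal"])).sum()
        ),
    }
    return {"pedigree": ped, "phenotypes": phen, "panel": panel,
            "diagnostics": diagnostics}


def provenance_record(cfg: PipelineConfig, seed: int | None, paths) -> dict:
    """Machine-readable run record: config, seed, input checksums."""
    checks = {}
    for p in paths:
        p = Path(p)
        if p.exists():
            checks[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return {"config": d, "seed": seed, "input_sha256": checks}


def write_provenance(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
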