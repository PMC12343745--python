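"""File formats: VCF genotype panels, coordinate tables, YAML run configs.

VCF is written as plain VCF 4.2 text (diploid GT, one contig per linkage
group, QTL effect annotated through the INFO key ``QTL``) and read back with
cyvcf2.  REF/ALT are placeholder alleles A/T; dosage counts ALT copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


@dataclass
class GenotypePanel:
    """Dosage matrix with individual and locus annotations."""

    dosages: np.ndarray  # (n_individuals, n_loci), values 0/1/2
    individual_ids: list[str]
    loci: pd.DataFrame  # columns chrom, pos, is_qtl, effect

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.loci) != m:
            raise ValueError("locus table length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        for chrom, grp in self.loci.groupby("chrom"):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def __eq__(self, other):
        return (
            isinstance(other, GenotypePanel)
            and np.array_equal(self.dosages, other.dosages)
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.loci["chrom"].to_numpy(), other.loci["chrom"].to_numpy())
            and np.array_equal(self.loci["pos"].to_numpy(), other.loci["pos"].to_numpy())
            and np.array_equal(self.loci["is_qtl"].to_numpy(), other.loci["is_qtl"].to_numpy())
            and np.allclose(self.loci["effect"].to_numpy(), other.loci["effect"].to_numpy())
        )


def panel_from_sim(sim_result) -> GenotypePanel:
    """Build a GenotypePanel from a SimResult."""
    return GenotypePanel(
        dosages=sim_result.genotypes,
        individual_ids=list(sim_result.sample_table["id"]),
        loci=sim_result.locus_table[["chrom", "pos", "is_qtl", "effect"]].copy(),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as uncompressed VCF 4.2."""
    path = Path(path)
    chroms = sorted(panel.loci["chrom"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geaplus\n")
        for c in chroms:
            length = int(panel.loci.loc[panel.loci["chrom"] == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=QTL,Number=1,Type=Float,Description="Additive QTL effect">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.individual_ids) + "\n")
        chrom_arr = panel.loci["chrom"].to_numpy()
        pos_arr = panel.loci["pos"].to_numpy()
        qtl_arr = panel.loci["is_qtl"].to_numpy()
        eff_arr = panel.loci["effect"].to_numpy()
        for j in range(panel.n_loci):
            info = f"QTL={eff_arr[j]:.6g}" if qtl_arr[j] else "."
            gts = "\t".join(_GT[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{chrom_arr[j]}\t{pos_arr[j]}\tlocus_{j}\tA\tT\t.\t.\t{info}\tGT\t{gts}\n")


def read_vcf(path) -> GenotypePanel:
    """Read a diploid GT-only VCF into a GenotypePanel.

    Haploid or missing genotypes raise a descriptive error naming the sample
    and locus.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    dosages: list[np.ndarray] = []
    chroms: list[int] = []
    positions: list[int] = []
    is_qtl: list[bool] = []
    effects: list[float] = []
    for var in vcf:
        gt = var.genotype.array()
        if gt.shape[1] < 3:
            bad = samples[0]
            raise ValueError(f"{path}: non-diploid GT at {var.CHROM}:{var.POS} (sample {bad})")
        alleles = gt[:, :2]
        if np.any(alleles < 0):
            bad = samples[int(np.argmax((alleles < 0).any(axis=1)))]
            raise ValueError(f"{path}: missing or haploid GT for sample {bad} at {var.CHROM}:{var.POS}")
        dosages.append(alleles.sum(axis=1).astype(np.int8))
        chroms.append(int(var.CHROM))
        positions.append(int(var.POS))
        eff = var.INFO.get("QTL")
        is_qtl.append(eff is not None)
        effects.append(float(eff) if eff is not None else 0.0)
    if not dosages:
        raise ValueError(f"{path}: VCF contains no variant records")
    loci = pd.DataFrame({"chrom": chroms, "pos": positions, "is_qtl": is_qtl, "effect": effects})
    return GenotypePanel(np.column_stack(dosages), samples, loci)


def write_coords(table: pd.DataFrame, path) -> None:
    """Write an id/lon/lat table (plus any extra columns) as headered CSV."""
    cols = ["id", "lon", "lat"] + [c for c in table.columns if c not in ("id", "lon", "lat")]
    table[cols].to_csv(path, index=False)


def read_coords(path) -> pd.DataFrame:
    """Read a coordinate CSV with id, lon, lat headers.

    Rows with unparsable or out-of-range coordinates are rejected with their
    row numbers; duplicate ids raise.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "lon", "lat"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if bad.any():
        rows = ", ".join(str(i + 2) for i in df.index[bad])  # +2: header + 1-based
        raise ValueError(f"{path}: invalid coordinates at row(s) {rows}")
    if df["id"].duplicated().any():
        dups = ", ".join(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"{path}: duplicate id(s) {dups}")
    df["lon"] = lon
    df["lat"] = lat
    return df


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


class MaskParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    site_frac: float = 0.5
    n_train_per_site: int = 5

    @field_validator("site_frac")
    @classmethod
    def _frac(cls, v):
        if not (0.0 < v <= 1.0):
            raise ValueError("site_frac must be in (0, 1]")
        return v


class PredictorParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_folds: int = 10
    n_replicates: int = 8
    hidden_layer_sizes: tuple[int, ...] = (128, 64)
    dropout: float = 0.1
    learning_rate: float = 5e-3
    max_epochs: int = 600
    patience: int = 50
    batch_size: Optional[int] = 32


class ScanParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    methods: list[str] = Field(
        default_factory=lambda: ["LM_naive", "LM_P", "LM_RR", "LM_PRR", "RDA_simple", "RDA_partial", "IND_LRT"]
    )
    alpha: float = 0.005
    maf_post_sim: float = 0.005
    maf_pre_scan: float = 0.01
    d_thresh_km: float = 10.0
    sd_frac: float = 0.01
    r2_prune: float = 0.2
    k_pc: int = 3


class RasterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    extent: tuple[float, float, float, float] = (34.0, 48.0, 30.0, 40.0)
    resolution: float = 0.25
    gradient: tuple[float, float, float] = (0.0, 0.25, 0.15)
    n_bumps: int = 6
    bump_amplitude: float = 0.5
    bump_scale_deg: float = 3.0


class LandscapeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_candidate_sites: int = 200
    site_inset_deg: float = 1.0  # keep sites away from the raster edge
    min_spacing_km: float = 40.0
    m0_km: float = 1.0
    m_total: float = 0.01
    refugium_coords: list[tuple[float, float]] = Field(
        default_factory=lambda: [(35.5, 32.0), (47.0, 34.0)]
    )


class RunConfig(BaseModel):
    """Validated run configuration for the full experiment."""

    model_config = ConfigDict(extra="forbid")

    profile: str = "mini"
    sim_overrides: dict = Field(default_factory=dict)
    scenario: str = "1R"  # 1R or 2R
    raster: RasterParams = Field(default_factory=RasterParams)
    landscape: LandscapeParams = Field(default_factory=LandscapeParams)
    mask: MaskParams = Field(default_factory=MaskParams)
    predictor: PredictorParams = Field(default_factory=PredictorParams)
    scan: ScanParams = Field(default_factory=ScanParams)
    schemes: list[str] = Field(default_factory=lambda: ["regular", "geaplus", "perfect_geaplus"])
    seeds: list[int] = Field(default_factory=lambda: [1])
    n_mask_replicates: int = 1
    out_dir: Optional[str] = None

    @field_validator("scenario")
    @classmethod
    def _scen(cls, v):
        if v not in ("1R", "2R"):
            raise ValueError("scenario must be 1R or 2R")
        return v

    @field_validator("sim_overrides")
    @classmethod
    def _overrides(cls, v):
        from .simulate import SimConfig

        allowed = set(SimConfig.__dataclass_fields__)
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown sim override key(s): {sorted(unknown)}")
        if "outcrossing_rate" in v and not (0.0 <= v["outcrossing_rate"] <= 1.0):
            raise ValueError("outcrossing_rate must be in [0, 1]")
        return v


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; an empty file gives all
    defaults and unknown keys are rejected listing the offenders."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig(**raw)
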