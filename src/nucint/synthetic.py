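"""Synthetic data generators with known ground truth.

Every downstream stage of the package (AP-MS scoring, BiFC image
classification, qPCR relative quantification) can be exercised against data
produced here, where the planted interactors, the per-cell localization
labels, or the true fold changes are known exactly.

Three generators:

* :func:`generate_apms_counts` — replicate AP-MS hit tables (spectral counts
  and sequence coverage for bait IP vs no-antibody control, two epitope tags
  times three biological replicates) with a planted set of true interactors.
* :func:`generate_bifc_field` — two-channel (DAPI, Venus) 16-bit microscopy
  fields of non-overlapping cells with nuclear or cytoplasmic reporter signal.
* :func:`generate_qpcr_table` — Ct tables for a target and a reference gene
  across groups with stated true expression fold changes.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

#: Column contract for AP-MS hit tables, shared with :mod:`nucint.apms`.
HIT_TABLE_COLUMNS = (
    "protein_id",
    "tag",
    "replicate",
    "fraction",
    "ip_peptide_count",
    "nac_peptide_count",
    "ip_coverage_pct",
)


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class ApmsSimConfig:
    """Generative model for replicate AP-MS hit tables.

    Spectral counts are Poisson around the configured means; sequence
    coverage is truncated-normal on (0, 100].  A non-interactor ("background")
    protein binds non-specifically, so its expected peptide count is the same
    in the IP and in the no-antibody control (NAC).  A planted interactor is
    enriched ``enrichment_fold``-fold in the IP, and a fraction
    ``nac_leak_fraction`` of that IP signal leaks into the NAC.  The bait has
    its own (high) IP mean.  With ``deterministic=True`` every count equals
    its rounded mean and coverage equals ``coverage_base_pct`` exactly — the
    noiseless limit used by exact-recovery tests.
    """

    n_background: int = 200
    n_true: int = 20
    n_replicates_per_tag: int = 3
    tags: tuple[str, ...] = ("GFP", "HA")
    fractions: tuple[str, ...] = ("nuclear",)
    background_count_mean: float = 5.0
    enrichment_fold: float = 10.0
    nac_leak_fraction: float = 0.05
    coverage_base_pct: float = 25.0
    coverage_sd_pct: float = 8.0
    bait_id: str = "Moesin"
    bait_ip_count: float = 60.0
    bait_nac_count: float = 3.0
    dropout_prob: float = 0.1
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_background >= 0, "n_background", "must be >= 0")
        _require(self.n_true >= 0, "n_true", "must be >= 0")
        _require(self.n_replicates_per_tag >= 1, "n_replicates_per_tag", "must be >= 1")
        _require(len(self.tags) >= 1, "tags", "must be non-empty")
        _require(len(self.fractions) >= 1, "fractions", "must be non-empty")
        _require(self.background_count_mean >= 0, "background_count_mean", "must be >= 0")
        _require(self.enrichment_fold > 1, "enrichment_fold", "must be > 1")
        _require(0 <= self.nac_leak_fraction <= 1, "nac_leak_fraction", "must be in [0, 1]")
        _require(0 < self.coverage_base_pct <= 100, "coverage_base_pct", "must be in (0, 100]")
        _require(self.coverage_sd_pct >= 0, "coverage_sd_pct", "must be >= 0")
        _require(0 <= self.dropout_prob < 1, "dropout_prob", "must be in [0, 1)")
        _require(self.bait_ip_count >= 0, "bait_ip_count", "must be >= 0")
        _require(self.bait_nac_count >= 0, "bait_nac_count", "must be >= 0")


@dataclass(frozen=True)
class ImageSimConfig:
    """Geometry and intensity model for synthetic two-channel BiFC fields.

    Nuclei are disks of ``nucleus_radius_px``; the cytoplasm is the annulus
    out to ``cell_radius_px``.  Cells are placed by rejection sampling with a
    minimum centre distance of ``2 * cell_radius_px`` so ground truth is
    separable.  Grey levels are on the 16-bit camera scale.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    nucleus_radius_px: int = 8
    cell_radius_px: int = 14
    dapi_level: float = 20000.0
    venus_nuclear_level: float = 12000.0
    venus_cyto_level: float = 12000.0
    background_level: float = 300.0
    noise_sd: float = 50.0
    fraction_positive: float = 0.6
    fraction_nuclear_of_positive: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.field_shape) == 2 and min(self.field_shape) > 0,
                 "field_shape", "must be two positive pixel counts")
        _require(self.n_cells >= 0, "n_cells", "must be >= 0")
        _require(self.cell_radius_px > self.nucleus_radius_px,
                 "cell_radius_px", "must exceed nucleus_radius_px")
        _require(self.nucleus_radius_px > 0, "nucleus_radius_px", "must be > 0")
        for name in ("dapi_level", "venus_nuclear_level", "venus_cyto_level",
                     "background_level"):
            _require(0 <= getattr(self, name) <= 65535, name, "must be in [0, 65535]")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(0 <= self.fraction_positive <= 1, "fraction_positive", "must be in [0, 1]")
        _require(0 <= self.fraction_nuclear_of_positive <= 1,
                 "fraction_nuclear_of_positive", "must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to each synthetic dataset.

    ``true_interactors`` is set in AP-MS mode; ``cell_labels`` in image mode
    (one record per cell: ``cell_id``, centre ``row``/``col`` and the label
    ``negative`` / ``nuclear`` / ``cytoplasmic``).
    """

    true_interactors: frozenset[str] | None = None
    bait_id: str | None = None
    cell_labels: list[dict] | None = None

    def to_json(self) -> str:
        payload = {
            "true_interactors": sorted(self.true_interactors)
            if self.true_interactors is not None else None,
            "bait_id": self.bait_id,
            "cell_labels": self.cell_labels,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        interactors = payload.get("true_interactors")
        return cls(
            true_interactors=frozenset(interactors) if interactors is not None else None,
            bait_id=payload.get("bait_id"),
            cell_labels=payload.get("cell_labels"),
        )


# ---------------------------------------------------------------------------
# AP-MS hit tables
# ---------------------------------------------------------------------------

def generate_apms_counts(config: ApmsSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate replicate AP-MS hit tables with planted interactors.

    Returns a tidy table with the :data:`HIT_TABLE_COLUMNS` contract — one
    row per protein per (tag, replicate, fraction) sample — and the truth
    record naming the planted interactors.  Proteins undetected in a sample
    (count drawn as zero, or dropped out) appear with zero count and zero
    coverage; the bait is always detected.
    """
    rng = np.random.default_rng(config.seed)
    true_ids = [f"INT{i + 1:03d}" for i in range(config.n_true)]
    background_ids = [f"BG{i + 1:04d}" for i in range(config.n_background)]
    proteins = [config.bait_id] + true_ids + background_ids
    true_set = frozenset(true_ids)

    ip_means = np.empty(len(proteins))
    nac_means = np.empty(len(proteins))
    planted_ip_mean = config.background_count_mean * config.enrichment_fold
    for i, pid in enumerate(proteins):
        if pid == config.bait_id:
            ip_means[i] = config.bait_ip_count
            nac_means[i] = config.bait_nac_count
        elif pid in true_set:
            ip_means[i] = planted_ip_mean
            nac_means[i] = config.nac_leak_fraction * planted_ip_mean
        else:
            ip_means[i] = config.background_count_mean
            nac_means[i] = config.background_count_mean

    frames = []
    for fraction in config.fractions:
        for tag in config.tags:
            for rep in range(1, config.n_replicates_per_tag + 1):
                if config.deterministic:
                    ip = np.round(ip_means).astype(int)
                    nac = np.round(nac_means).astype(int)
                    cov = np.full(len(proteins), config.coverage_base_pct)
                else:
                    ip = rng.poisson(ip_means)
                    nac = rng.poisson(nac_means)
                    cov = np.clip(
                        rng.normal(config.coverage_base_pct, config.coverage_sd_pct,
                                   len(proteins)),
                        0.1, 100.0,
                    )
                    drop = rng.random(len(proteins)) < config.dropout_prob
                    drop &= np.asarray(proteins) != config.bait_id
                    ip = np.where(drop, 0, ip)
                cov = np.where(ip == 0, 0.0, cov)
                frames.append(pd.DataFrame({
                    "protein_id": proteins,
                    "tag": tag,
                    "replicate": rep,
                    "fraction": fraction,
                    "ip_peptide_count": ip,
                    "nac_peptide_count": nac,
                    "ip_coverage_pct": np.round(cov, 3),
                }))
    table = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(true_interactors=true_set, bait_id=config.bait_id)
    return table, truth


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as TSV with the canonical header."""
    table.loc[:, list(HIT_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BiFC microscopy fields
# ---------------------------------------------------------------------------

def _place_centres(rng: np.random.Generator, config: ImageSimConfig) -> np.ndarray:
    """Rejection-sample non-overlapping cell centres (min distance 2 * cell radius)."""
    margin = config.cell_radius_px + 1
    rows, cols = config.field_shape
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise GenerationError(
            "field too small for the configured cell radius; "
            "enlarge field_shape or shrink cells")
    min_d2 = (2 * config.cell_radius_px) ** 2
    centres: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(config.n_cells, 1)
    while len(centres) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {config.n_cells} non-overlapping cells in "
                f"{rows}x{cols}; request fewer cells or a larger field")
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_d2 for rr, cc in centres):
            centres.append((r, c))
    return np.array(centres).reshape(-1, 2)


def generate_bifc_field(
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Simulate one two-channel field of cells with known localization labels.

    The DAPI channel carries a disk of ``dapi_level`` at every nucleus.  The
    Venus channel is painted per cell according to its drawn label: a nuclear
    disk for nuclear-positive cells, a cytoplasmic annulus for
    cytoplasmic-positive cells, nothing for negative cells.  Gaussian noise of
    ``noise_sd`` grey levels is added to both channels before clipping to the
    16-bit range.

    Returns ``(dapi, venus, truth)`` with both images ``uint16`` arrays of
    ``config.field_shape``.
    """
    rng = np.random.default_rng(config.seed)
    centres = _place_centres(rng, config)

    positive = rng.random(config.n_cells) < config.fraction_positive
    nuclear = rng.random(config.n_cells) < config.fraction_nuclear_of_positive
    labels = np.where(~positive, "negative", np.where(nuclear, "nuclear", "cytoplasmic"))

    rows, cols = config.field_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dapi = np.full(config.field_shape, config.background_level, dtype=float)
    venus = np.full(config.field_shape, config.background_level, dtype=float)

    cell_records = []
    for i in range(config.n_cells):
        cr, cc0 = centres[i]
        d2 = (rr - cr) ** 2 + (cc - cc0) ** 2
        nucleus = d2 <= config.nucleus_radius_px ** 2
        annulus = (d2 > config.nucleus_radius_px ** 2) & (d2 <= config.cell_radius_px ** 2)
        dapi[nucleus] = config.dapi_level
        if labels[i] == "nuclear":
            venus[nucleus] = config.venus_nuclear_level
        elif labels[i] == "cytoplasmic":
            venus[annulus] = config.venus_cyto_level
        cell_records.append({
            "cell_id": i + 1,
            "row": float(cr),
            "col": float(cc0),
            "label": str(labels[i]),
        })

    if config.noise_sd > 0:
        dapi += rng.normal(0.0, config.noise_sd, config.field_shape)
        venus += rng.normal(0.0, config.noise_sd, config.field_shape)
    dapi = np.clip(np.round(dapi), 0, 65535).astype(np.uint16)
    venus = np.clip(np.round(venus), 0, 65535).astype(np.uint16)
    return dapi, venus, SyntheticTruth(cell_labels=cell_records)


def write_field(
    dapi: np.ndarray,
    venus: np.ndarray,
    truth: SyntheticTruth,
    out_dir: str | Path,
    prefix: str = "field",
) -> dict[str, Path]:
    """Write a field as two single-channel 16-bit TIFFs plus a truth JSON sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dapi": out / f"{prefix}_dapi.tif",
        "venus": out / f"{prefix}_venus.tif",
        "truth": out / f"{prefix}_truth.json",
    }
    tifffile.imwrite(paths["dapi"], dapi.astype(np.uint16))
    tifffile.imwrite(paths["venus"], venus.astype(np.uint16))
    paths["truth"].write_text(truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_qpcr_table(
    true_fold_changes: Sequence[float],
    n_reps: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    *,
    group_names: Sequence[str] | None = None,
    target_gene: str = "target",
    reference_gene: str = "Rp49",
    base_target_ct: float = 24.0,
    base_reference_ct: float = 18.0,
    n_technical: int = 2,
) -> pd.DataFrame:
    """Simulate a tidy qPCR Ct table for groups with known expression folds.

    ``true_fold_changes[g]`` is group g's target expression relative to the
    first (control) group, whose fold is conventionally 1.  A fold f shifts
    the target Ct by ``-log2(f)`` cycles (more template amplifies earlier);
    the reference gene is constant across groups.  Gaussian noise of
    ``ct_noise_sd`` cycles is added per well; each (sample, gene) is measured
    ``n_technical`` times, mirroring technical PCR repetitions.

    Returns a DataFrame with columns ``sample, group, gene, role, ct``.
    """
    folds = np.asarray(true_fold_changes, dtype=float)
    if folds.ndim != 1 or len(folds) < 1:
        raise ConfigurationError("true_fold_changes: must be a non-empty sequence")
    if np.any(folds <= 0):
        raise ConfigurationError("true_fold_changes: all folds must be > 0")
    if n_reps < 1:
        raise ConfigurationError("n_reps: must be >= 1")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd: must be >= 0")
    if group_names is None:
        group_names = ["control"] + [f"group{g}" for g in range(1, len(folds))]
    if len(group_names) != len(folds):
        raise ConfigurationError("group_names: length must match true_fold_changes")

    rng = np.random.default_rng(seed)
    rows = []
    for g, (group, fold) in enumerate(zip(group_names, folds)):
        target_ct_mean = base_target_ct - math.log2(fold)
        for rep in range(1, n_reps + 1):
            sample = f"{group}_r{rep}"
            for _ in range(n_technical):
                rows.append((sample, group, target_gene, "target",
                             target_ct_mean + rng.normal(0, ct_noise_sd)))
                rows.append((sample, group, reference_gene, "reference",
                             base_reference_ct + rng.normal(0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "role", "ct"])
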