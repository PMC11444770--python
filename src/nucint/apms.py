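"""Composite AP-MS interaction scoring.

A bait protein is immunoprecipitated from a cell fraction alongside a
no-antibody control (NAC); co-purifying proteins are identified by LC-MS/MS
and semi-quantified by spectral (peptide) counting.  Each candidate protein
receives a composite score

    S = FC × v × E

where, aggregated over the six biological replicate samples (three per
epitope tag),

* ``FC`` — fold change of peptide count, IP over NAC,
* ``v``  — sequence coverage % of the protein,
* ``E``  — IP efficiency: the bait protein's own IP-over-NAC peptide-count
  enrichment, a per-sample quality factor applied to every protein in that
  sample.

Candidates are ranked by descending score and membership of an annotated
complex (e.g. Mediator) among the top N is summarized.

The ratio underlying FC and E uses a configurable zero-denominator policy;
the default floors the denominator at one count, keeping plain-ratio
semantics for detected controls while leaving proteins undetected in the NAC
finite and strongly scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import BaitNotDetectedError, TableFormatError
from .synthetic import HIT_TABLE_COLUMNS

RatioPolicy = str  # "floor" | "pseudocount"

#: Columns of the ranked results table.
RESULT_COLUMNS = (
    "protein_id", "fold_change", "coverage_pct", "ip_efficiency",
    "score", "rank", "n_replicates_detected",
)


@dataclass(frozen=True)
class ReplicateObservation:
    """One protein's detection in one (tag, replicate, fraction) sample."""

    protein_id: str
    tag: str
    replicate: int
    fraction: str
    ip_peptide_count: int
    nac_peptide_count: int
    ip_coverage_pct: float


@dataclass(frozen=True)
class ScoreComponents:
    """The three factors of the composite score, aggregated over samples."""

    fold_change: float
    coverage_pct: float
    ip_efficiency: float


@dataclass(frozen=True)
class ScoreRecord:
    protein_id: str
    components: ScoreComponents
    score: float
    rank: int
    n_replicates_detected: int


@dataclass(frozen=True)
class ComplexAnnotation:
    """User-supplied membership list of an annotated protein complex."""

    complex_name: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("member_ids: complex annotation must be non-empty")


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_hit_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a replicate hit table (TSV).

    ``column_map`` maps canonical column names to the names used in a foreign
    table (e.g. a supplementary table exported from a search engine), so such
    tables can be ingested without editing.  Validation rejects missing
    columns, negative counts, coverage outside [0, 100] and duplicate
    (tag, replicate, fraction, protein) keys; messages cite the 1-based data
    row.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.loc[:, list(HIT_TABLE_COLUMNS)]
    return validate_observations(df, source=str(path))


def validate_observations(df: pd.DataFrame, source: str = "table") -> pd.DataFrame:
    """Validate an in-memory observation table against the value contract."""
    for col in ("ip_peptide_count", "nac_peptide_count"):
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        if bad.size:
            raise TableFormatError(
                f"{source}: negative {col} on row {bad[0] + 1}")
    cov = df["ip_coverage_pct"].to_numpy(dtype=float)
    bad = np.flatnonzero((cov < 0) | (cov > 100))
    if bad.size:
        raise TableFormatError(
            f"{source}: ip_coverage_pct outside [0, 100] on row {bad[0] + 1}")
    key = ["tag", "replicate", "fraction", "protein_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TableFormatError(
            f"{source}: duplicate (tag, replicate, fraction, protein_id) key "
            f"on row {row + 1}")
    return df.reset_index(drop=True)


def read_hit_tables(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Read several hit tables and concatenate them into one validated table."""
    frames = [read_hit_table(p) for p in paths]
    merged = pd.concat(frames, ignore_index=True)
    return validate_observations(merged, source="merged tables")


# ---------------------------------------------------------------------------
# score arithmetic
# ---------------------------------------------------------------------------

def fold_change(c_ip: float, c_nac: float, policy: RatioPolicy = "floor") -> float:
    """Peptide-count fold change of the IP over the no-antibody control.

    ``floor`` (default): ``c_ip / max(c_nac, 1)``.  ``pseudocount``:
    ``(c_ip + 1) / (c_nac + 1)``.
    """
    if c_ip < 0 or c_nac < 0:
        raise ValueError("peptide counts must be non-negative")
    if policy == "floor":
        return c_ip / max(c_nac, 1)
    if policy == "pseudocount":
        return (c_ip + 1) / (c_nac + 1)
    raise ValueError(f"unknown ratio policy {policy!r}")


def ip_efficiency(bait_ip_count: float, bait_nac_count: float,
                  policy: RatioPolicy = "floor") -> float:
    """Bait enrichment IP vs NAC — the per-sample IP quality factor.

    Same ratio rule as :func:`fold_change`, applied to the bait's counts.
    """
    return fold_change(bait_ip_count, bait_nac_count, policy)


def sample_efficiencies(
    observations: pd.DataFrame,
    bait_id: str,
    policy: RatioPolicy = "floor",
) -> dict[tuple[str, int], float]:
    """IP efficiency per (tag, replicate) sample from the bait's rows.

    Raises :class:`BaitNotDetectedError` if the bait is missing (or has zero
    IP count) in any sample present in the table.
    """
    samples = observations[["tag", "replicate"]].drop_duplicates()
    bait_rows = observations[observations["protein_id"] == bait_id]
    out: dict[tuple[str, int], float] = {}
    for tag, rep in samples.itertuples(index=False):
        row = bait_rows[(bait_rows["tag"] == tag) & (bait_rows["replicate"] == rep)]
        if row.empty or int(row["ip_peptide_count"].iloc[0]) == 0:
            raise BaitNotDetectedError(
                f"bait not detected: {bait_id!r} absent from IP sample "
                f"(tag={tag}, replicate={rep})")
        out[(tag, rep)] = ip_efficiency(
            float(row["ip_peptide_count"].iloc[0]),
            float(row["nac_peptide_count"].iloc[0]),
            policy,
        )
    return out


def aggregate_components(
    protein_obs: pd.DataFrame,
    efficiencies: Mapping[tuple[str, int], float],
    policy: RatioPolicy = "floor",
    pooled: bool = False,
) -> tuple[ScoreComponents, int]:
    """Aggregate one protein's observations over all samples.

    Per-sample fold change and coverage are computed with missing samples
    imputed as zero count / zero coverage, then averaged over every sample in
    ``efficiencies`` (the full replicate design, normally six).  With
    ``pooled=True`` the counts are summed across samples before a single
    ratio is formed instead.  The efficiency factor is the mean of the
    per-sample bait efficiencies and does not depend on the protein.

    Returns the aggregated components and the number of samples in which the
    protein was detected (IP count > 0).
    """
    if protein_obs.empty:
        raise ValueError("no observations for protein")
    n_samples = len(efficiencies)
    by_sample = {
        (tag, rep): (float(ip), float(nac), float(cov))
        for tag, rep, ip, nac, cov in protein_obs[
            ["tag", "replicate", "ip_peptide_count", "nac_peptide_count",
             "ip_coverage_pct"]
        ].itertuples(index=False)
    }
    fcs, covs = [], []
    ip_total = nac_total = 0.0
    n_detected = 0
    for key in efficiencies:
        ip, nac, cov = by_sample.get(key, (0.0, 0.0, 0.0))
        fcs.append(fold_change(ip, nac, policy))
        covs.append(cov)
        ip_total += ip
        nac_total += nac
        if ip > 0:
            n_detected += 1
    # plain sequential sums keep the arithmetic reproducible by naive loops
    fc = fold_change(ip_total, nac_total, policy) if pooled else sum(fcs) / len(fcs)
    components = ScoreComponents(
        fold_change=fc,
        coverage_pct=sum(covs) / len(covs),
        ip_efficiency=sum(efficiencies.values()) / len(efficiencies),
    )
    return components, n_detected


def score(components: ScoreComponents) -> float:
    """Composite interaction score: fold change × coverage % × IP efficiency."""
    return components.fold_change * components.coverage_pct * components.ip_efficiency


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def score_proteins(
    observations: pd.DataFrame,
    bait_id: str,
    fraction: str = "nuclear",
    policy: RatioPolicy = "floor",
    pooled: bool = False,
    include_bait: bool = False,
) -> pd.DataFrame:
    """Score and rank every protein observed in one cell fraction.

    Runs the full composite-score pipeline: per-sample bait efficiencies,
    per-protein aggregation over the replicate design, the three-factor
    product, and descending-score ranking (ties broken by higher fold change,
    then protein id).  The bait itself is excluded from the candidate list
    unless ``include_bait`` is set.

    Returns a DataFrame with :data:`RESULT_COLUMNS`, ordered by rank.
    """
    obs = observations[observations["fraction"] == fraction]
    if obs.empty:
        raise ValueError(f"no observations for fraction {fraction!r}")
    effs = sample_efficiencies(obs, bait_id, policy)
    rows = []
    for pid, group in obs.groupby("protein_id", sort=False):
        if pid == bait_id and not include_bait:
            continue
        comps, n_det = aggregate_components(group, effs, policy, pooled)
        rows.append((pid, comps.fold_change, comps.coverage_pct,
                     comps.ip_efficiency, score(comps), n_det))
    result = pd.DataFrame(
        rows,
        columns=["protein_id", "fold_change", "coverage_pct", "ip_efficiency",
                 "score", "n_replicates_detected"],
    )
    return rank_proteins(result)


def rank_proteins(records: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..N by descending score; ties by fold change, then id."""
    if records.empty:
        raise ValueError("cannot rank an empty record set")
    ordered = records.sort_values(
        by=["score", "fold_change", "protein_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered.loc[:, list(RESULT_COLUMNS)]


def complex_membership_summary(
    ranked: pd.DataFrame,
    annotation: ComplexAnnotation,
    top_n: int,
) -> dict:
    """Count annotated complex members among the top-N ranked candidates.

    Returns ``{"complex_name", "top_n", "n_in_top_n", "member_ranks"}`` where
    ``member_ranks`` lists ``(protein_id, rank)`` for every detected member,
    best rank first.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(ranked):
        raise ValueError(f"top_n={top_n} exceeds list length {len(ranked)}")
    members = ranked[ranked["protein_id"].isin(annotation.member_ids)]
    member_ranks = sorted(
        (str(pid), int(rank))
        for pid, rank in members[["protein_id", "rank"]].itertuples(index=False)
    )
    member_ranks.sort(key=lambda t: t[1])
    return {
        "complex_name": annotation.complex_name,
        "top_n": int(top_n),
        "n_in_top_n": int((members["rank"] <= top_n).sum()),
        "member_ranks": member_ranks,
    }


def write_results(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked results table as TSV."""
    ranked.loc[:, list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)
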