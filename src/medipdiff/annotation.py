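"""Genomic annotation model: probes, promoters and their cross-links.

Coordinates are 0-based half-open (BED convention) internally; writers
that produce human-facing reports convert to 1-based inclusive.  Promoter
regions are defined in transcription orientation around the TSS: 1000 bp
upstream to 250 bp downstream, so minus-strand promoters extend downstream
in genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UPSTREAM_BP",
    "DOWNSTREAM_BP",
    "GenomicAnnotation",
    "promoter_region",
    "read_annotation",
    "write_annotation",
]

#: Extent of the tiled promoter region relative to the TSS, in
#: transcription orientation.
UPSTREAM_BP = 1000
DOWNSTREAM_BP = 250

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "promoter_id"]
PROMOTER_COLUMNS = [
    "promoter_id",
    "gene_symbol",
    "chrom",
    "tss",
    "strand",
    "region_start",
    "region_end",
    "cpg_count",
    "c_count",
    "g_count",
    "length_bp",
]


def promoter_region(tss: int, strand: str) -> tuple[int, int]:
    """Return the (start, end) of the tiled region around a TSS.

    The region spans ``UPSTREAM_BP`` upstream to ``DOWNSTREAM_BP``
    downstream of the TSS in transcription orientation, clipped at 0.
    """
    if strand == "+":
        start, end = tss - UPSTREAM_BP, tss + DOWNSTREAM_BP
    elif strand == "-":
        start, end = tss - DOWNSTREAM_BP, tss + UPSTREAM_BP
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return max(start, 0), end


@dataclass
class GenomicAnnotation:
    """Probe and promoter coordinates plus the probe-to-promoter map.

    Attributes
    ----------
    chromosome_lengths
        Mapping chromosome name -> length in bp.
    probes
        DataFrame with columns ``probe_id, chrom, start, end, promoter_id``.
    promoters
        DataFrame with columns ``promoter_id, gene_symbol, chrom, tss,
        strand, region_start, region_end, cpg_count, c_count, g_count,
        length_bp``.
    """

    chromosome_lengths: dict[str, int]
    probes: pd.DataFrame
    promoters: pd.DataFrame

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)[PROBE_COLUMNS]
        self.promoters = self.promoters.reset_index(drop=True)[PROMOTER_COLUMNS]
        self.validate()

    def validate(self) -> None:
        probes, promoters = self.probes, self.promoters
        if promoters["promoter_id"].duplicated().any():
            dup = promoters.loc[promoters["promoter_id"].duplicated(), "promoter_id"].iloc[0]
            raise ValueError(f"duplicated promoter_id {dup!r}")
        if probes["probe_id"].duplicated().any():
            dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicated probe_id {dup!r}")
        unknown_chrom = set(promoters["chrom"]) | set(probes["chrom"])
        unknown_chrom -= set(self.chromosome_lengths)
        if unknown_chrom:
            raise ValueError(f"chromosomes without length: {sorted(unknown_chrom)}")
        for df, what, lo, hi in (
            (promoters, "promoter region", "region_start", "region_end"),
            (probes, "probe", "start", "end"),
        ):
            if len(df) == 0:
                continue
            if (df[lo] < 0).any() or (df[lo] >= df[hi]).any():
                bad = df.loc[(df[lo] < 0) | (df[lo] >= df[hi])].iloc[0]
                raise ValueError(
                    f"{what} {bad.iloc[0]!r} has invalid interval [{bad[lo]}, {bad[hi]})"
                )
            lengths = df["chrom"].map(self.chromosome_lengths)
            if (df[hi] > lengths).any():
                bad = df.loc[df[hi] > lengths].iloc[0]
                raise ValueError(f"{what} {bad.iloc[0]!r} extends past its chromosome end")
        known = set(promoters["promoter_id"])
        missing = set(probes["promoter_id"]) - known
        if missing:
            raise ValueError(f"probes reference unknown promoters: {sorted(missing)[:5]}")
        if len(probes):
            merged = probes.merge(
                promoters[["promoter_id", "chrom", "region_start", "region_end"]],
                on="promoter_id",
                suffixes=("", "_prom"),
            )
            outside = (
                (merged["chrom"] != merged["chrom_prom"])
                | (merged["start"] < merged["region_start"])
                | (merged["end"] > merged["region_end"])
            )
            if outside.any():
                bad = merged.loc[outside, "probe_id"].iloc[0]
                raise ValueError(f"probe {bad!r} lies outside its promoter region")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    def probe_midpoints(self) -> pd.Series:
        """Interval midpoints of the probes (float bp), indexed by probe_id."""
        mid = (self.probes["start"] + self.probes["end"]) / 2.0
        return pd.Series(mid.to_numpy(), index=self.probes["probe_id"].to_numpy())


def _read_tsv(path: Path, columns: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {what} file {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} lacks columns {missing}")
    return df


def read_annotation(
    probe_path: str | Path,
    promoter_path: str | Path,
    chromosome_lengths: dict[str, int] | str | Path,
) -> GenomicAnnotation:
    """Read probe (BED6+promoter_id) and promoter (TSV) annotation files.

    Parameters
    ----------
    probe_path
        BED6-compatible TSV with header
        ``chrom start end probe_id score strand promoter_id``.
    promoter_path
        TSV with header ``promoter_id gene_symbol chrom tss strand
        cpg_count c_count g_count length_bp``.
    chromosome_lengths
        Mapping, or path to a two-column TSV ``chrom length``.
    """
    if not isinstance(chromosome_lengths, dict):
        genome = _read_tsv(Path(chromosome_lengths), ["chrom", "length"], "chromosome-length")
        chromosome_lengths = {
            row.chrom: int(row.length) for row in genome.itertuples(index=False)
        }

    probes_raw = _read_tsv(
        Path(probe_path),
        ["chrom", "start", "end", "probe_id", "score", "strand", "promoter_id"],
        "probe annotation",
    )
    proms_raw = _read_tsv(
        Path(promoter_path),
        ["promoter_id", "gene_symbol", "chrom", "tss", "strand", "cpg_count",
         "c_count", "g_count", "length_bp"],
        "promoter table",
    )

    def to_int(df: pd.DataFrame, col: str, what: str) -> pd.Series:
        try:
            return df[col].astype(int)
        except ValueError as exc:
            bad = df[col][~df[col].str.fullmatch(r"-?\d+")]
            line = bad.index[0] + 2  # +1 header, +1 1-based
            raise ValueError(
                f"{what}: non-integer {col}={bad.iloc[0]!r} at line {line}"
            ) from exc

    promoters = pd.DataFrame(
        {
            "promoter_id": proms_raw["promoter_id"],
            "gene_symbol": proms_raw["gene_symbol"],
            "chrom": proms_raw["chrom"],
            "tss": to_int(proms_raw, "tss", "promoter table"),
            "strand": proms_raw["strand"],
            "cpg_count": to_int(proms_raw, "cpg_count", "promoter table"),
            "c_count": to_int(proms_raw, "c_count", "promoter table"),
            "g_count": to_int(proms_raw, "g_count", "promoter table"),
            "length_bp": to_int(proms_raw, "length_bp", "promoter table"),
        }
    )
    bad_strand = ~promoters["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = promoters.index[bad_strand][0] + 2
        raise ValueError(f"promoter table: invalid strand at line {line}")
    regions = [
        promoter_region(t, s) for t, s in zip(promoters["tss"], promoters["strand"])
    ]
    promoters["region_start"] = [r[0] for r in regions]
    promoters["region_end"] = [r[1] for r in regions]

    probes = pd.DataFrame(
        {
            "probe_id": probes_raw["probe_id"],
            "chrom": probes_raw["chrom"],
            "start": to_int(probes_raw, "start", "probe annotation"),
            "end": to_int(probes_raw, "end", "probe annotation"),
            "promoter_id": probes_raw["promoter_id"],
        }
    )
    return GenomicAnnotation(chromosome_lengths, probes, promoters)


def write_annotation(annotation: GenomicAnnotation, probe_path: str | Path,
                     promoter_path: str | Path, genome_path: str | Path) -> None:
    """Write annotation files in the exact format `read_annotation` accepts."""
    probes = annotation.probes
    bed = pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "start": probes["start"],
            "end": probes["end"],
            "probe_id": probes["probe_id"],
            "score": 0,
            "strand": "+",
            "promoter_id": probes["promoter_id"],
        }
    )
    bed.to_csv(probe_path, sep="\t", index=False)
    annotation.promoters[
        ["promoter_id", "gene_symbol", "chrom", "tss", "strand",
         "cpg_count", "c_count", "g_count", "length_bp"]
    ].to_csv(promoter_path, sep="\t", index=False)
    genome = pd.DataFrame(
        sorted(annotation.chromosome_lengths.items()), columns=["chrom", "length"]
    )
    genome.to_csv(genome_path, sep="\t", index=False)
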