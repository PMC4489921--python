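"""Plain-text readers and writers for the pipeline's artefacts.

Contacts travel as (optionally gzipped) TSV triplets ``bin_i bin_j
count``; annotations as BED (0-based half-open); per-bin tracks and 4C
coverage as bedGraph; tables as TSV.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .genome import GenomeModel


def write_contacts(counts: ContactMatrix, path: str | Path) -> None:
    path = Path(path)
    trip = counts.to_triplets()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        trip.to_csv(fh, sep="\t", header=False, index=False)


def read_contacts(
    path: str | Path, bin_size: int, n_bins: int, max_offset: int
) -> ContactMatrix:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        trip = pd.read_csv(
            fh, sep="\t", header=None, names=["bin_i", "bin_j", "count"]
        )
    return ContactMatrix.from_triplets(trip, bin_size, n_bins, max_offset)


def write_bed(
    intervals: pd.DataFrame, path: str | Path, chrom: str = "chrSim"
) -> None:
    """Write start/end(/name) columns as BED."""
    cols = ["start", "end"] + (["name"] if "name" in intervals.columns else [])
    out = intervals[cols].reset_index(drop=True)
    out.insert(0, "chrom", chrom)
    out.to_csv(path, sep="\t", header=False, index=False)


def write_genome_annotation(genome: GenomeModel, outdir: str | Path) -> None:
    """Sites, domains and genes of a GenomeModel as BED files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bs = genome.bin_size
    sites = pd.DataFrame(
        {
            "start": genome.sites["position"],
            "end": genome.sites["position"] + 1,
            "name": genome.sites["class"],
        }
    )
    write_bed(sites, outdir / "sites.bed")
    doms = pd.DataFrame(
        {
            "start": genome.domains["start_bin"] * bs,
            "end": genome.domains["end_bin"] * bs,
            "name": genome.domains["class"],
        }
    )
    write_bed(doms, outdir / "domains.bed")
    genes = pd.DataFrame(
        {
            "start": genome.genes["tss"],
            "end": genome.genes["tss"] + 1,
            "name": "gene_" + genome.genes.index.astype(str),
        }
    )
    write_bed(genes, outdir / "genes.bed")


def write_bedgraph(
    values: np.ndarray,
    bin_size: int,
    path: str | Path,
    chrom: str = "chrSim",
) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    idx = np.nonzero(np.isfinite(values))[0]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": idx * bin_size,
            "end": (idx + 1) * bin_size,
            "value": np.asarray(values)[idx],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, bin_size: int, n_bins: int) -> np.ndarray:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    out = np.full(n_bins, np.nan)
    out[df["start"].to_numpy() // bin_size] = df["value"].to_numpy()
    return out
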