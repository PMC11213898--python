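"""Plasmid-mode NAT screening and GC-deviation genomic-island detection.

Plasmid screening is the translated genome search run at the relaxed 40%
identity threshold that maximizes non-redundant hits in plasmid databases.
Island detection is a sliding-window GC scan: windows whose GC content
deviates from the replicon mean by at least ``z_threshold`` standard
deviations (and by at least ``min_delta`` in absolute GC, a floor that keeps
pure sampling noise from being flagged) are merged into maximal runs.  This
compositional detector is an explicit, documented proxy for codon-usage /
HMM-based island finders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homology_search import SearchHit, translated_genome_search
from .nat_annotate import NatLocus
from .synthetic_data import GenomeRecord


@dataclass(frozen=True)
class GCProfile:
    contig: str
    window: int
    step: int
    starts: np.ndarray  # window start coordinates
    values: np.ndarray  # per-window GC fraction
    genome_mean: float
    genome_sd: float


@dataclass(frozen=True)
class IslandCall:
    contig: str
    span: tuple[int, int]
    mean_gc: float
    direction: str  # "low" | "high"
    z: float  # standard deviations from the genome mean


def plasmid_screen(
    query: str,
    plasmids: list[GenomeRecord],
    min_identity: float = 40.0,
    max_evalue: float = 1e-6,
) -> tuple[list[SearchHit], dict[str, int]]:
    """Screen plasmids for NAT-like genes at a relaxed identity threshold.

    Returns all hits plus per-plasmid hit counts (plasmids may carry more
    than one NAT gene).  Non-plasmid replicons are rejected by name.
    """
    for rep in plasmids:
        if rep.replicon_class != "plasmid":
            raise ValueError(
                f"replicon {rep.replicon_id} has class "
                f"{rep.replicon_class!r}, expected 'plasmid'"
            )
    hits: list[SearchHit] = []
    counts: dict[str, int] = {}
    for rep in plasmids:
        rep_hits = translated_genome_search(
            query, rep, min_identity=min_identity, max_evalue=max_evalue)
        counts[rep.replicon_id] = len(rep_hits)
        hits.extend(rep_hits)
    return hits, counts


def gc_profile(genome: GenomeRecord, window: int = 1000,
               step: int = 500) -> list[GCProfile]:
    """Per-contig sliding-window GC profile.  The number of windows on a
    contig of length L is floor((L - window) / step) + 1."""
    if window < step:
        raise ValueError(f"window ({window}) must be >= step ({step})")
    profiles = []
    all_values = []
    per_contig = []
    for rec in genome.contigs:
        seq = rec.sequence
        if len(seq) < window:
            raise ValueError(
                f"window ({window}) exceeds contig {rec.id} length "
                f"({len(seq)})"
            )
        is_gc = np.frombuffer(seq.encode(), dtype="S1")
        gc_ind = np.isin(is_gc, [b"G", b"C"]).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(gc_ind)])
        n_windows = (len(seq) - window) // step + 1
        starts = np.arange(n_windows) * step
        values = (csum[starts + window] - csum[starts]) / window
        per_contig.append((rec.id, starts, values))
        all_values.append(values)
    concat = np.concatenate(all_values)
    mean = float(concat.mean())
    sd = float(concat.std(ddof=0))
    for contig, starts, values in per_contig:
        profiles.append(GCProfile(
            contig=contig, window=window, step=step, starts=starts,
            values=values, genome_mean=mean, genome_sd=sd,
        ))
    return profiles


def detect_gc_islands(
    genome: GenomeRecord,
    window: int = 1000,
    step: int = 500,
    z_threshold: float = 2.0,
    min_delta: float = 0.05,
) -> list[IslandCall]:
    """Detect GC-deviant genomic islands.

    A window is flagged when its GC deviates from the replicon mean by at
    least ``z_threshold`` standard deviations and by at least ``min_delta``
    absolute GC fraction; adjacent or overlapping flagged windows of the
    same direction merge into one maximal call.
    """
    calls: list[IslandCall] = []
    for prof in gc_profile(genome, window=window, step=step):
        dev = prof.values - prof.genome_mean
        flagged = (np.abs(dev) >= z_threshold * prof.genome_sd) & \
                  (np.abs(dev) >= min_delta)
        run_start = None
        run_dir = None
        run_values: list[float] = []

        def emit(run_start, last_start, run_dir, run_values):
            span = (int(prof.starts[run_start]),
                    int(prof.starts[last_start]) + window)
            mean_gc = float(np.mean(run_values))
            z = ((mean_gc - prof.genome_mean) / prof.genome_sd
                 if prof.genome_sd > 0 else 0.0)
            calls.append(IslandCall(
                contig=prof.contig, span=span, mean_gc=mean_gc,
                direction=run_dir, z=float(z),
            ))

        for idx in range(len(prof.values)):
            if flagged[idx]:
                direction = "low" if dev[idx] < 0 else "high"
                if run_start is None:
                    run_start, run_dir, run_values = idx, direction, []
                elif direction != run_dir:
                    emit(run_start, idx - 1, run_dir, run_values)
                    run_start, run_dir, run_values = idx, direction, []
                run_values.append(prof.values[idx])
            elif run_start is not None:
                emit(run_start, idx - 1, run_dir, run_values)
                run_start, run_dir, run_values = None, None, []
        if run_start is not None:
            emit(run_start, len(prof.values) - 1, run_dir, run_values)
    return calls


def intersect_islands(
    islands: list[IslandCall], loci: list[NatLocus]
) -> pd.DataFrame:
    """All (locus, island) pairs with >= 1 base of overlap, with the exact
    overlap length in bases."""
    rows = []
    for locus in loci:
        l_start = min(s for s, _, _ in locus.segments)
        l_end = max(e for _, e, _ in locus.segments)
        for isl in islands:
            if isl.contig != locus.contig:
                continue
            overlap = min(l_end, isl.span[1]) - max(l_start, isl.span[0])
            if overlap >= 1:
                rows.append({
                    "locus_id": locus.locus_id,
                    "contig": locus.contig,
                    "island_start": isl.span[0],
                    "island_end": isl.span[1],
                    "island_direction": isl.direction,
                    "overlap_bases": overlap,
                })
    return pd.DataFrame(rows, columns=[
        "locus_id", "contig", "island_start", "island_end",
        "island_direction", "overlap_bases",
    ])
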