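"""Sequence processing: multiplexed reads -> per-individual MOTU detections.

The stages mirror a standard amplicon workflow for gut-content
metabarcoding: split reads by forward/reverse multiplex identifier
(MID) tags and strip tags and primers, filter by template length,
collapse each individual's reads into unique haplotypes discarding
rare ones, pool haplotypes across individuals and cluster them into
molecular operational taxonomic units (MOTUs) by greedy centroid
clustering over a grid of similarity thresholds, pick the optimal
threshold, and assign taxonomy to MOTU representatives against a
barcode reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import pairwise_identity
from .synthdata import BarcodeDB, ReadBatch, reverse_complement

#: Similarity grid over which MOTU clustering is repeated (0.97 down to 0.87).
DEFAULT_THRESHOLD_GRID = tuple(round(0.97 - 0.01 * i, 2) for i in range(11))

RANK_ORDER = ("species", "genus", "family", "order")


@dataclass
class HaplotypeTable:
    """Unique haplotypes per individual after trimming and filtering.

    ``per_individual`` maps individual -> {haplotype sequence -> copy count};
    all counts are >= the ``min_copies`` used to build the table.
    """

    per_individual: dict[str, dict[str, int]]
    min_copies: int = 2

    def pooled(self) -> list[tuple[str, int, dict[str, int]]]:
        """Pool across individuals: (sequence, total copies, origin counts)."""
        agg: dict[str, dict[str, int]] = {}
        for ind, haps in self.per_individual.items():
            for seq, n in haps.items():
                agg.setdefault(seq, {})[ind] = n
        return [(seq, sum(orig.values()), orig) for seq, orig in agg.items()]

    @property
    def n_haplotypes(self) -> int:
        return len({s for haps in self.per_individual.values() for s in haps})


@dataclass
class MOTUCluster:
    motu_id: str
    representative: str
    #: (haplotype sequence, individual of origin, copy count)
    members: list[tuple[str, str, int]]


@dataclass
class Assignment:
    status: str  # assigned | no_match | contaminant
    taxon: str | None = None
    rank: str | None = None
    identity: float = 0.0


@dataclass
class MOTUTable:
    threshold: float
    clusters: list[MOTUCluster]
    assignment: dict[str, Assignment] = field(default_factory=dict)

    @property
    def n_motus(self) -> int:
        return len(self.clusters)

    def individuals_of(self, motu_id: str) -> set[str]:
        for c in self.clusters:
            if c.motu_id == motu_id:
                return {ind for _, ind, _ in c.members}
        raise KeyError(motu_id)


@dataclass
class ThresholdDiagnostics:
    """Per-threshold MOTU and assignment counts used for threshold choice."""

    table: pd.DataFrame  # threshold, n_motus, species_with_multiple_motus, n_species_assignments

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def demultiplex(
    reads: ReadBatch | Sequence[tuple[str, str]],
    mid_pairs: Mapping[tuple[str, str], str] | None = None,
    max_mismatch: int = 0,
    mid_length: int = 10,
    forward_primer: str | None = None,
    reverse_primer: str | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Split reads by MID pair and trim tags and primers.

    A read is assigned iff both its forward MID (read prefix) and its
    reverse MID (reverse complement of the read suffix) match a
    registered pair within ``max_mismatch`` substitutions.  Assigned
    reads are returned trimmed to the template (adaptors, primers and
    MIDs removed).  Returns ``(individual -> template sequences,
    unassigned reads)``.
    """
    if isinstance(reads, ReadBatch):
        batch = reads
        mid_pairs = batch.mid_pairs if mid_pairs is None else mid_pairs
        mid_length = batch.mid_length
        forward_primer = batch.forward_primer if forward_primer is None else forward_primer
        reverse_primer = batch.reverse_primer if reverse_primer is None else reverse_primer
        read_list = batch.reads
    else:
        read_list = list(reads)
        if mid_pairs is None or forward_primer is None or reverse_primer is None:
            raise ValueError("mid_pairs and primers are required for raw read lists")

    individuals = list(mid_pairs.values())
    if len(set(individuals)) != len(individuals):
        raise ValueError("duplicate individual in MID pair map")
    if len(set(mid_pairs)) != len(mid_pairs):
        raise ValueError("duplicate MID pair in map")

    fwd_registry = sorted({f for f, _ in mid_pairs})
    rev_registry = sorted({r for _, r in mid_pairs})

    def match_mid(observed: str, registry: list[str]) -> str | None:
        if max_mismatch == 0:
            return observed if observed in registry else None
        best, best_d = None, max_mismatch + 1
        for m in registry:
            d = sum(a != b for a, b in zip(observed, m))
            if d < best_d:
                best, best_d = m, d
        return best if best_d <= max_mismatch else None

    fwd_set = set(fwd_registry)
    rev_set = set(rev_registry)
    flen, rlen = len(forward_primer), len(reverse_primer)
    assigned: dict[str, list[str]] = {ind: [] for ind in individuals}
    unassigned: list[str] = []
    for _, seq in read_list:
        fmid_obs = seq[:mid_length]
        rmid_obs = reverse_complement(seq[-mid_length:])
        fmid = fmid_obs if fmid_obs in fwd_set else match_mid(fmid_obs, fwd_registry)
        rmid = rmid_obs if rmid_obs in rev_set else match_mid(rmid_obs, rev_registry)
        ind = mid_pairs.get((fmid, rmid)) if fmid and rmid else None
        if ind is None:
            unassigned.append(seq)
        else:
            template = seq[mid_length + flen : len(seq) - mid_length - rlen]
            assigned[ind].append(template)
    return assigned, unassigned


def length_filter(
    reads: Iterable[str] | Mapping[str, list[str]],
    min_len: int = 260,
    max_len: int = 300,
):
    """Keep sequences with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if isinstance(reads, Mapping):
        return {ind: [s for s in seqs if min_len <= len(s) <= max_len] for ind, seqs in reads.items()}
    return [s for s in reads if min_len <= len(s) <= max_len]


def collapse_haplotypes(
    reads_by_individual: Mapping[str, Iterable[str]],
    min_copies: int = 2,
) -> HaplotypeTable:
    """Collapse each individual's reads to unique haplotypes; drop those
    seen fewer than ``min_copies`` times."""
    per_individual: dict[str, dict[str, int]] = {}
    for ind, seqs in reads_by_individual.items():
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        kept = {s: n for s, n in counts.items() if n >= min_copies}
        if kept:
            per_individual[ind] = kept
    return HaplotypeTable(per_individual=per_individual, min_copies=min_copies)


def cluster_motus(haplotypes: HaplotypeTable, threshold: float) -> MOTUTable:
    """Greedy centroid clustering of pooled haplotypes.

    Haplotypes are processed in decreasing total copy count (ties broken
    by lexicographic sequence order); each joins the first existing
    centroid with identity >= threshold, otherwise founds a new cluster
    whose representative it becomes.  The result is therefore invariant
    to input order.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pooled = haplotypes.pooled()
    pooled.sort(key=lambda item: (-item[1], item[0]))
    clusters: list[MOTUCluster] = []
    for seq, total, origins in pooled:
        placed = False
        for c in clusters:
            if pairwise_identity(seq, c.representative) >= threshold:
                c.members.extend((seq, ind, n) for ind, n in sorted(origins.items()))
                placed = True
                break
        if not placed:
            clusters.append(
                MOTUCluster(
                    motu_id=f"motu{len(clusters) + 1:04d}",
                    representative=seq,
                    members=[(seq, ind, n) for ind, n in sorted(origins.items())],
                )
            )
    return MOTUTable(threshold=threshold, clusters=clusters)


def _best_hits(seq: str, db: BarcodeDB, mode: str = "global") -> list[tuple[float, object]]:
    """(identity, record) for every reference record, best first."""
    scored = [(pairwise_identity(seq, rec.sequence, mode=mode), rec) for rec in db.records]
    scored.sort(key=lambda x: (-x[0], x[1].taxon_id))
    return scored


def _consensus_assignment(hits: list[tuple[float, object]], tie_window: float) -> Assignment:
    """Assign at species rank if the top hits agree on species, else at
    the lowest rank shared by all hits within ``tie_window`` identity of
    the best hit (mirroring a lowest-common-ancestor consensus)."""
    best_id, best_rec = hits[0]
    window = [rec for ident, rec in hits if ident >= best_id - tie_window]
    for rank in RANK_ORDER:
        names = {rec.lineage.get(rank, rec.species_label) for rec in window}
        if len(names) == 1:
            return Assignment(status="assigned", taxon=best_rec.taxon_id if rank == "species" else names.pop(), rank=rank, identity=best_id)
    return Assignment(status="no_match", identity=best_id)


def assign_taxonomy(
    representatives: Mapping[str, str] | Sequence[str],
    db: BarcodeDB,
    min_identity: float = 0.98,
    tie_window: float = 0.005,
) -> dict[str, Assignment]:
    """Best-hit taxonomic assignment of MOTU representatives.

    A representative is assigned only when its best reference identity
    exceeds ``min_identity`` (strictly).  If the best hit is a
    contaminant record the MOTU is flagged ``contaminant``; hits within
    ``tie_window`` of the best are used for a rank consensus.
    """
    if not db.records:
        raise ValueError("empty barcode database")
    if not isinstance(representatives, Mapping):
        representatives = {f"motu{i + 1:04d}": s for i, s in enumerate(representatives)}
    out: dict[str, Assignment] = {}
    for motu_id, seq in representatives.items():
        hits = _best_hits(seq, db)
        best_id, best_rec = hits[0]
        if best_id <= min_identity:
            out[motu_id] = Assignment(status="no_match", identity=best_id)
        elif best_rec.is_contaminant:
            out[motu_id] = Assignment(status="contaminant", taxon=best_rec.taxon_id, identity=best_id)
        else:
            out[motu_id] = _consensus_assignment(hits, tie_window)
    return out


def flag_chimeras(
    representatives: Mapping[str, str],
    db: BarcodeDB,
    min_identity: float = 0.98,
) -> set[str]:
    """Split-best-hit chimera screen.

    A MOTU representative is flagged chimeric when its two halves each
    produce a local best hit with identity >= ``min_identity`` and those
    hits name different (non-contaminant) taxa.
    """
    flagged = set()
    for motu_id, seq in representatives.items():
        half = len(seq) // 2
        if half < 20:
            continue
        hits_a = _best_hits(seq[:half], db, mode="local")
        hits_b = _best_hits(seq[half:], db, mode="local")
        (id_a, rec_a), (id_b, rec_b) = hits_a[0], hits_b[0]
        if id_a >= min_identity and id_b >= min_identity and rec_a.taxon_id != rec_b.taxon_id:
            flagged.add(motu_id)
    return flagged


def threshold_diagnostics(
    haplotypes: HaplotypeTable,
    db: BarcodeDB,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    min_identity: float = 0.98,
) -> tuple[pd.DataFrame, dict[float, tuple[MOTUTable, dict[str, Assignment]]]]:
    """Cluster and assign at every grid threshold, collecting the counts
    that drive threshold selection."""
    rows = []
    per_threshold: dict[float, tuple[MOTUTable, dict[str, Assignment]]] = {}
    for t in grid:
        table = cluster_motus(haplotypes, t)
        reps = {c.motu_id: c.representative for c in table.clusters}
        assignments = assign_taxonomy(reps, db, min_identity=min_identity)
        table.assignment = assignments
        chimeric = flag_chimeras(reps, db, min_identity=min_identity)
        species_counts: dict[str, int] = {}
        species_assigned: set[str] = set()
        for motu_id, a in assignments.items():
            if a.status == "assigned" and a.rank == "species":
                species_assigned.add(a.taxon)
                if motu_id not in chimeric:
                    species_counts[a.taxon] = species_counts.get(a.taxon, 0) + 1
        multi = sum(1 for n in species_counts.values() if n > 1)
        # distinct species retained at species rank: merging two species
        # into one MOTU pushes its assignment up-rank and loses a species
        n_species_assignments = len(species_assigned)
        rows.append(
            {
                "threshold": t,
                "n_motus": table.n_motus,
                "species_with_multiple_motus": multi,
                "n_species_assignments": n_species_assignments,
            }
        )
        per_threshold[t] = (table, assignments)
    return pd.DataFrame(rows), per_threshold


def select_threshold(
    haplotypes: HaplotypeTable,
    db: BarcodeDB,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    min_identity: float = 0.98,
    majority_fraction: float = 0.5,
) -> tuple[float, ThresholdDiagnostics]:
    """Pick the clustering threshold that minimises the number of species
    split across multiple MOTUs (chimeric MOTUs excluded) while retaining
    the majority of species-level assignments.

    "Majority" is operationalised as >= ``majority_fraction`` of the
    maximum species-assignment count over the grid; ties go to the
    higher threshold.
    """
    if not grid:
        raise ValueError("threshold grid is empty")
    if haplotypes.n_haplotypes == 0:
        raise ValueError("no haplotypes to cluster")
    diag, _ = threshold_diagnostics(haplotypes, db, grid, min_identity)
    max_assign = diag["n_species_assignments"].max()
    eligible = diag[diag["n_species_assignments"] >= majority_fraction * max_assign]
    eligible = eligible.sort_values(["species_with_multiple_motus", "threshold"], ascending=[True, False])
    t_opt = float(eligible.iloc[0]["threshold"])
    return t_opt, ThresholdDiagnostics(table=diag)


def detections_table(table: MOTUTable, assignments: dict[str, Assignment] | None = None) -> pd.DataFrame:
    """Per-individual MOTU detections as a tidy table.

    Columns: individual_id, motu_id, taxon, rank, status, identity,
    n_haplotypes, n_reads.  One row per (individual, MOTU) pair.
    """
    assignments = assignments if assignments is not None else table.assignment
    rows = []
    for c in table.clusters:
        a = assignments.get(c.motu_id, Assignment(status="no_match"))
        per_ind: dict[str, tuple[int, int]] = {}
        for seq, ind, n in c.members:
            haps, reads = per_ind.get(ind, (0, 0))
            per_ind[ind] = (haps + 1, reads + n)
        for ind, (haps, nreads) in sorted(per_ind.items()):
            rows.append(
                {
                    "individual_id": ind,
                    "motu_id": c.motu_id,
                    "taxon": a.taxon,
                    "rank": a.rank,
                    "status": a.status,
                    "identity": a.identity,
                    "n_haplotypes": haps,
                    "n_reads": nreads,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "motu_id", "taxon", "rank", "status", "identity", "n_haplotypes", "n_reads"],
    )


def process_reads(
    batch: ReadBatch,
    db: BarcodeDB,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    min_copies: int = 2,
    min_len: int = 260,
    max_len: int = 300,
    min_identity: float = 0.98,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, float, ThresholdDiagnostics]:
    """Full read-processing pipeline: demultiplex -> length filter ->
    haplotype collapse -> threshold selection -> detections at the
    optimal threshold.  Returns (detections, t_opt, diagnostics)."""
    assigned, _ = demultiplex(batch, max_mismatch=max_mismatch)
    filtered = length_filter(assigned, min_len, max_len)
    haplotypes = collapse_haplotypes(filtered, min_copies=min_copies)
    t_opt, diagnostics = select_threshold(haplotypes, db, grid, min_identity)
    table = cluster_motus(haplotypes, t_opt)
    reps = {c.motu_id: c.representative for c in table.clusters}
    assignments = assign_taxonomy(reps, db, min_identity=min_identity)
    table.assignment = assignments
    return detections_table(table, assignments), t_opt, diagnostics
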