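"""Synthetic data generator for the diet-metabarcoding pipeline.

Generates every input the pipeline consumes, with known ground truth:

* a barcode reference of prey, predator and contaminant taxa carrying a
  ~287 bp marker sequence,
* kick-sample style prey abundance tables along a land-use intensity
  gradient,
* per-individual gut contents drawn from local prey availability with
  multiplicative taxon selection weights (weights of 1 recover the
  proportional-consumption null),
* noisy multiplexed amplicon reads tagged with forward/reverse multiplex
  identifiers (MIDs), including predator self-DNA, contaminant reads,
  substitution errors and single-breakpoint chimeras.

All operations are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import pairwise_identity

NUCLEOTIDES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Folmer-region style CO1 primers used to frame simulated amplicons.
FORWARD_PRIMER = "GGTCAACAAATCATAAAGATATTGG"
REVERSE_PRIMER = "ACTTATATTGTTTATACGAGGGAA"

RANKS = ("species", "genus", "family", "order")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeRecord:
    """One reference sequence with its taxonomy."""

    taxon_id: str
    species_label: str
    rank: str
    sequence: str
    is_predator: bool = False
    is_contaminant: bool = False
    #: rank -> name, species through order, for multi-hit consensus.
    lineage: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be over {A,C,G,T}")


@dataclass
class BarcodeDB:
    """Reference barcode database; ground truth for assignment and simulation."""

    records: list[BarcodeRecord]
    within_identity_floor: float = 1.0
    between_identity_ceiling: float = 0.0

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon_id, None)
        return list(seen)

    @property
    def prey_taxa(self) -> list[str]:
        return [t for t in self.taxa if not self._any(t, "is_predator") and not self._any(t, "is_contaminant")]

    @property
    def predator_taxa(self) -> list[str]:
        return [t for t in self.taxa if self._any(t, "is_predator")]

    @property
    def contaminant_taxa(self) -> list[str]:
        return [t for t in self.taxa if self._any(t, "is_contaminant")]

    def _any(self, taxon: str, attr: str) -> bool:
        return any(getattr(r, attr) for r in self.records if r.taxon_id == taxon)

    def sequences_for(self, taxon: str) -> list[str]:
        return [r.sequence for r in self.records if r.taxon_id == taxon]

    def to_fasta(self, path: str | Path) -> None:
        """Write records as FASTA with ``>taxon_id|species_label|rank`` headers."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = []
        for i, r in enumerate(self.records):
            header = f"{r.taxon_id}|{r.species_label}|{r.rank}"
            recs.append(SeqRecord(Seq(r.sequence), id=header, description=""))
        seqio_write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        predator_taxa: Iterable[str] = (),
        contaminant_taxa: Iterable[str] = (),
    ) -> "BarcodeDB":
        from Bio.SeqIO import parse

        predators = set(predator_taxa)
        contaminants = set(contaminant_taxa)
        records = []
        for rec in parse(str(path), "fasta"):
            # species labels may contain spaces, so use the whole header
            header = rec.description or rec.id
            parts = header.split("|")
            if len(parts) != 3:
                raise ValueError(f"barcode header {rec.id!r} is not 'taxon_id|species_label|rank'")
            taxon_id, label, rank = (p.strip() for p in parts)
            records.append(
                BarcodeRecord(
                    taxon_id=taxon_id,
                    species_label=label,
                    rank=rank,
                    sequence=str(rec.seq).upper(),
                    is_predator=taxon_id in predators,
                    is_contaminant=taxon_id in contaminants,
                )
            )
        return cls(records)


@dataclass(frozen=True)
class TaxonResponse:
    """One taxon's abundance response to the intensity gradient."""

    taxon_id: str
    response: str  # increasing | decreasing | flat
    baseline_abundance: float
    response_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.response not in ("increasing", "decreasing", "flat"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.baseline_abundance < 0:
            raise ValueError("baseline_abundance must be >= 0")


@dataclass
class CommunityScenario:
    """Sites along an intensity gradient plus per-taxon response curves."""

    sites: list[tuple[str, float]]  # (site_id, intensity score)
    taxa: list[TaxonResponse]
    seasons: list[str] = field(default_factory=lambda: ["spring"])

    def expected_abundance(self, taxon: TaxonResponse, intensity: float) -> float:
        """Log-linear response to centred intensity; never negative."""
        scores = np.array([s[1] for s in self.sites], dtype=float)
        x = intensity - scores.mean()
        sign = {"increasing": 1.0, "decreasing": -1.0, "flat": 0.0}[taxon.response]
        return taxon.baseline_abundance * math.exp(sign * abs(taxon.response_slope) * x)


@dataclass
class GutTruth:
    """Ground-truth gut contents of one simulated predator individual."""

    individual_id: str
    predator_species: str
    site_id: str
    season: str
    consumed: frozenset[str]
    selection_weights_used: Mapping[str, float]


@dataclass
class ReadBatch:
    """Multiplexed amplicon reads plus the sidecar truth table."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    mid_pairs: dict[tuple[str, str], str]  # (forward MID, reverse MID) -> individual
    truth: pd.DataFrame  # read_id, individual_id, category, taxon_id
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    mid_length: int = 10

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f">{read_id}\n{seq}\n")

    def to_fastq(self, path: str | Path, quality: int = 30) -> None:
        qchar = chr(quality + 33)
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_mid_map(self, path: str | Path) -> None:
        rows = [
            {"forward_mid": f, "reverse_mid": r, "individual_id": ind}
            for (f, r), ind in self.mid_pairs.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Substitute exactly n_sites positions, each to a different base."""
    if n_sites == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_sites, replace=False)
    for p in pos:
        options = [b for b in "ACGT" if b != arr[p]]
        arr[p] = options[rng.integers(3)]
    return "".join(arr)


def generate_mids(n: int, length: int = 10, min_distance: int = 3, seed: int = 0) -> list[str]:
    """Greedy set of MID tags with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    mids: list[str] = []
    attempts = 0
    while len(mids) < n:
        candidate = _random_sequence(rng, length)
        if all(sum(a != b for a, b in zip(candidate, m)) >= min_distance for m in mids):
            mids.append(candidate)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not construct MID set; relax the distance constraint")
    return mids


def generate_reference_db(
    n_prey_taxa: int,
    haplotypes_per_taxon: int = 2,
    seq_length: int = 287,
    between_taxon_divergence: float = 0.10,
    within_taxon_divergence: float = 0.01,
    seed: int = 0,
    n_contaminant_taxa: int = 1,
) -> BarcodeDB:
    """Generate a barcode reference with two predators and >=1 contaminant.

    Taxon consensus sequences radiate from a common ancestor on a star
    phylogeny: each branch accumulates ``between/2 * L`` substitutions,
    so unrelated taxa differ at roughly ``between`` of their sites.
    Haplotypes within a taxon carry ``within/2 * L`` substitutions off
    the consensus, guaranteeing intra-taxon identity of at least
    ``1 - within``.  Pairs of taxa that end up closer than
    ``1 - 0.7 * between`` identity are redrawn, so the between-taxon
    identity ceiling holds on every generated fixture.  Contaminant
    taxa (human-like off-target templates) are drawn from independent
    random sequences.
    """
    if not (0 <= within_taxon_divergence < between_taxon_divergence <= 0.3):
        raise ValueError("need 0 <= within < between <= 0.3")
    if n_prey_taxa < 2:
        raise ValueError("need at least two prey taxa")
    rng = np.random.default_rng(seed)

    ancestor = _random_sequence(rng, seq_length)
    branch_sites = max(1, round(between_taxon_divergence / 2 * seq_length))
    within_sites = round(within_taxon_divergence / 2 * seq_length)
    ceiling = 1.0 - 0.7 * between_taxon_divergence
    floor = 1.0 - 2 * within_sites / seq_length

    def hamming_identity(a: str, b: str) -> float:
        return sum(x == y for x, y in zip(a, b)) / len(a)

    names = [f"prey{i + 1:02d}" for i in range(n_prey_taxa)]
    names += ["predatorA", "predatorB"]
    consensuses: dict[str, str] = {}
    for name in names:
        for _ in range(200):
            cand = _mutate(rng, ancestor, branch_sites)
            if all(hamming_identity(cand, other) <= ceiling for other in consensuses.values()):
                consensuses[name] = cand
                break
        else:
            raise RuntimeError("could not satisfy between-taxon divergence; lower n_prey_taxa or raise divergence")

    records: list[BarcodeRecord] = []
    for i, name in enumerate(names):
        is_pred = name.startswith("predator")
        if is_pred:
            label = "Predator alpha" if name == "predatorA" else "Predator beta"
            genus = label.split()[0] + ("A" if name == "predatorA" else "B")
        else:
            label = f"Genus{i + 1} species{i + 1}"
            genus = f"Genus{i + 1}"
        lineage = {
            "species": label,
            "genus": genus,
            "family": f"Family{i // 3 + 1}",
            "order": f"Order{i // 6 + 1}",
        }
        for _ in range(haplotypes_per_taxon):
            hap = _mutate(rng, consensuses[name], within_sites)
            records.append(
                BarcodeRecord(
                    taxon_id=name,
                    species_label=label,
                    rank="species",
                    sequence=hap,
                    is_predator=is_pred,
                    lineage=lineage,
                )
            )

    for j in range(n_contaminant_taxa):
        label = "Homo sapiens" if j == 0 else f"Contaminant{j + 1} sp."
        records.append(
            BarcodeRecord(
                taxon_id=f"contam{j + 1:02d}",
                species_label=label,
                rank="species",
                sequence=_random_sequence(rng, seq_length),
                is_contaminant=True,
                lineage={"species": label, "genus": label.split()[0], "family": f"ContamFam{j + 1}", "order": f"ContamOrd{j + 1}"},
            )
        )

    return BarcodeDB(records, within_identity_floor=floor, between_identity_ceiling=ceiling)


def default_scenario(
    n_sites: int = 10,
    n_taxa: int = 12,
    seasons: Sequence[str] = ("spring", "autumn"),
    baseline: float = 80.0,
    slope: float = 0.4,
    seed: int = 0,
) -> CommunityScenario:
    """A balanced gradient scenario: a third of taxa increase with
    intensity, a third decrease, a third are flat."""
    rng = np.random.default_rng(seed)
    sites = [(f"site{i + 1:02d}", float(i + 1)) for i in range(n_sites)]
    responses = ["increasing", "decreasing", "flat"]
    taxa = []
    for i in range(n_taxa):
        taxa.append(
            TaxonResponse(
                taxon_id=f"prey{i + 1:02d}",
                response=responses[i % 3],
                baseline_abundance=float(baseline * rng.uniform(0.5, 1.5)),
                response_slope=slope,
            )
        )
    return CommunityScenario(sites=sites, taxa=list(taxa), seasons=list(seasons))


def simulate_community(
    scenario: CommunityScenario,
    noise_dispersion: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-season x taxon count table with overdispersed noise.

    Counts follow a negative binomial with mean from the taxon's
    response curve and shape ``noise_dispersion`` (variance =
    mu + mu^2/dispersion).  ``noise_dispersion=None`` or ``inf`` gives
    the deterministic zero-noise limit (rounded means).
    """
    rng = np.random.default_rng(seed)
    deterministic = noise_dispersion is None or math.isinf(noise_dispersion)
    if not deterministic and noise_dispersion <= 0:
        raise ValueError("noise_dispersion must be positive (or None/inf for no noise)")
    rows = []
    index = []
    for site_id, intensity in scenario.sites:
        for season in scenario.seasons:
            counts = {}
            for taxon in scenario.taxa:
                mu = scenario.expected_abundance(taxon, intensity)
                if deterministic:
                    counts[taxon.taxon_id] = int(round(mu))
                elif mu == 0:
                    counts[taxon.taxon_id] = 0
                else:
                    # NB as Gamma-Poisson mixture
                    lam = rng.gamma(noise_dispersion, mu / noise_dispersion)
                    counts[taxon.taxon_id] = int(rng.poisson(lam))
            rows.append(counts)
            index.append((site_id, season))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["site_id", "season"]))
    return df[[t.taxon_id for t in scenario.taxa]]


@dataclass(frozen=True)
class ItemsPerGut:
    """Distribution of the number of distinct prey taxa per gut.

    ``kind="fixed"`` draws exactly ``mean`` items; ``kind="ztpoisson"``
    draws from a zero-truncated Poisson whose mean equals ``mean``.
    """

    kind: str = "ztpoisson"
    mean: float = 4.5

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "ztpoisson"):
            raise ValueError(f"unknown items-per-gut kind {self.kind!r}")
        if self.mean < 1:
            raise ValueError("mean items per gut must be >= 1")

    @property
    def _lambda(self) -> float:
        """Rate of the underlying Poisson such that the zero-truncated
        mean lambda/(1-exp(-lambda)) equals self.mean."""
        target = self.mean
        lo, hi = 1e-9, target
        for _ in range(200):
            mid = (lo + hi) / 2
            if mid / (1 - math.exp(-mid)) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(round(self.mean)), dtype=int)
        lam = self._lambda
        out = rng.poisson(lam, size=size)
        while (zero := out == 0).any():  # rejection for the truncation
            out[zero] = rng.poisson(lam, size=int(zero.sum()))
        return out


def simulate_guts(
    abundance_row: pd.Series | Mapping[str, float],
    predator_species: str,
    n_individuals: int,
    items_per_gut: ItemsPerGut | int = ItemsPerGut(),
    selection_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    site_id: str = "site01",
    season: str = "spring",
    id_prefix: str = "",
) -> list[GutTruth]:
    """Draw per-individual consumed taxon sets from local availability.

    Each gut draws its number of distinct prey taxa, then samples that
    many taxa without replacement with inclusion probability
    proportional to abundance x selection weight.  The predator's own
    taxon is excluded before renormalisation (cannibalism cannot be
    resolved molecularly).  Weights of 1 for every taxon recover the
    proportional-consumption null model.
    """
    abundance = pd.Series(abundance_row, dtype=float)
    if isinstance(items_per_gut, int):
        items_per_gut = ItemsPerGut(kind="fixed", mean=float(items_per_gut))
    weights = dict(selection_weights or {})
    available = abundance[(abundance > 0) & (abundance.index != predator_species)]
    if available.empty or abundance.sum() <= 0:
        raise ValueError("no prey available: abundance row is all zero or only the predator itself")
    for t, w in weights.items():
        if t in available.index and w <= 0:
            raise ValueError(f"selection weight for present taxon {t!r} must be > 0")

    w = np.array([weights.get(t, 1.0) for t in available.index])
    probs = available.to_numpy() * w
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    n_items = items_per_gut.draw(rng, n_individuals)
    n_items = np.minimum(n_items, len(available))

    guts = []
    taxa = np.array(available.index)
    logp = np.log(probs)
    for i in range(n_individuals):
        k = int(n_items[i])
        # Gumbel top-k == sequential weighted sampling without replacement
        keys = logp + rng.gumbel(size=len(taxa))
        consumed = frozenset(taxa[np.argsort(-keys)[:k]])
        guts.append(
            GutTruth(
                individual_id=f"{id_prefix}{predator_species}_{site_id}_{season}_{i + 1:03d}",
                predator_species=predator_species,
                site_id=site_id,
                season=season,
                consumed=consumed,
                selection_weights_used={t: weights.get(t, 1.0) for t in available.index},
            )
        )
    return guts


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for p in hits:
        options = [b for b in "ACGT" if b != arr[p]]
        arr[p] = options[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    guts: Sequence[GutTruth],
    db: BarcodeDB,
    mid_design: tuple[int, int] = (16, 15),
    reads_per_gut: int = 200,
    error_rate: float = 0.0,
    chimera_rate: float = 0.0,
    predator_dna_fraction: float = 0.0,
    contaminant_fraction: float = 0.0,
    seed: int = 0,
) -> ReadBatch:
    """Emit MID-tagged amplicon reads for every gut, with a truth sidecar.

    Each read is ``forward MID + forward primer + template +
    revcomp(reverse primer) + revcomp(reverse MID)``.  A read's template
    is, with the configured probabilities, the predator's own barcode, a
    contaminant barcode, a single-breakpoint chimera of two consumed
    templates, or (otherwise) the barcode of a uniformly chosen consumed
    taxon.  Substitution errors are applied per base at ``error_rate``.
    """
    n_forward, n_reverse = mid_design
    if n_forward * n_reverse < len(guts):
        raise ValueError(
            f"MID design ({n_forward} x {n_reverse}) provides {n_forward * n_reverse} "
            f"combinations but {len(guts)} individuals need tags"
        )
    rng = np.random.default_rng(seed)
    fwd_mids = generate_mids(n_forward, seed=int(rng.integers(2**31)))
    rev_mids = generate_mids(n_reverse, seed=int(rng.integers(2**31)))

    mid_pairs: dict[tuple[str, str], str] = {}
    for idx, gut in enumerate(guts):
        pair = (fwd_mids[idx // n_reverse], rev_mids[idx % n_reverse])
        mid_pairs[pair] = gut.individual_id

    all_pairs = {
        (f, r): mid_pairs.get((f, r), f"unused_{i}_{j}")
        for i, f in enumerate(fwd_mids)
        for j, r in enumerate(rev_mids)
    }

    contaminants = db.contaminant_taxa
    reads: list[tuple[str, str]] = []
    truth_rows = []
    pair_by_ind = {ind: pair for pair, ind in mid_pairs.items()}
    for gut in guts:
        fmid, rmid = pair_by_ind[gut.individual_id]
        consumed = sorted(gut.consumed)
        templates = {t: db.sequences_for(t) for t in consumed}
        own = db.sequences_for(gut.predator_species)
        for r in range(reads_per_gut):
            u = rng.random()
            if u < predator_dna_fraction and own:
                taxon = gut.predator_species
                template = own[rng.integers(len(own))]
                category = "predator"
            elif u < predator_dna_fraction + contaminant_fraction and contaminants:
                taxon = contaminants[rng.integers(len(contaminants))]
                seqs = db.sequences_for(taxon)
                template = seqs[rng.integers(len(seqs))]
                category = "contaminant"
            elif (
                u < predator_dna_fraction + contaminant_fraction + chimera_rate
                and len(consumed) >= 2
            ):
                t1, t2 = rng.choice(len(consumed), size=2, replace=False)
                s1 = templates[consumed[t1]][0]
                s2 = templates[consumed[t2]][0]
                bp = int(rng.integers(1, min(len(s1), len(s2))))
                template = s1[:bp] + s2[bp:]
                taxon = f"{consumed[t1]}+{consumed[t2]}"
                category = "chimera"
            else:
                taxon = consumed[rng.integers(len(consumed))]
                seqs = templates[taxon]
                template = seqs[rng.integers(len(seqs))]
                category = "prey"
            insert = _apply_errors(rng, template, error_rate)
            read = (
                fmid
                + FORWARD_PRIMER
                + insert
                + reverse_complement(REVERSE_PRIMER)
                + reverse_complement(rmid)
            )
            read_id = f"{gut.individual_id}_r{r + 1:04d}"
            reads.append((read_id, read))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "individual_id": gut.individual_id,
                    "category": category,
                    "taxon_id": taxon,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=["read_id", "individual_id", "category", "taxon_id"])
    batch = ReadBatch(reads=reads, mid_pairs=all_pairs, truth=truth)
    return batch


def guts_to_frame(guts: Sequence[GutTruth]) -> pd.DataFrame:
    """Tidy ground-truth table: one row per (individual, consumed taxon)."""
    rows = []
    for g in guts:
        for t in sorted(g.consumed):
            rows.append(
                {
                    "individual_id": g.individual_id,
                    "predator_species": g.predator_species,
                    "site_id": g.site_id,
                    "season": g.season,
                    "taxon_id": t,
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "predator_species", "site_id", "season", "taxon_id"])


def truth_incidence(guts: Sequence[GutTruth]) -> pd.DataFrame:
    """Binary individuals x taxa matrix of the simulated gut contents."""
    taxa = sorted({t for g in guts for t in g.consumed})
    data = np.zeros((len(guts), len(taxa)), dtype=int)
    for i, g in enumerate(guts):
        for t in g.consumed:
            data[i, taxa.index(t)] = 1
    return pd.DataFrame(data, index=[g.individual_id for g in guts], columns=taxa)
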