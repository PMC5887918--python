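"""Diet matrices and per-predator niche statistics.

All diet analyses are presence/absence based: read counts from gut
amplicons cannot reliably quantify how much of a prey was eaten, so a
cell records only whether a predator individual tested positive for a
prey taxon.  From the binary diet matrix this module derives
utilization vectors (proportion of positives per taxon), Levins'
standardized niche breadth, Pianka's pairwise niche overlap, and a
scalar selection-strength statistic comparing observed to null-expected
consumption frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("predator_species", "site_id", "season")


@dataclass
class DietMatrix:
    """Binary predator-individual x prey-taxon incidence with metadata.

    ``incidence`` is indexed by individual_id with prey-taxon columns;
    ``meta`` is indexed identically with predator_species, site_id and
    season columns.
    """

    incidence: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.incidence.index.equals(self.meta.index):
            raise ValueError("incidence and meta must share an index")
        vals = self.incidence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("diet matrix must be binary")

    @property
    def taxa(self) -> list[str]:
        return list(self.incidence.columns)

    def subset(self, **criteria) -> "DietMatrix":
        """Rows whose metadata match all given criteria
        (e.g. ``subset(predator_species="predatorA", site_id="site01")``)."""
        mask = pd.Series(True, index=self.meta.index)
        for key, value in criteria.items():
            if key not in self.meta.columns:
                raise KeyError(key)
            mask &= self.meta[key] == value
        return DietMatrix(self.incidence.loc[mask], self.meta.loc[mask])

    def positives(self) -> pd.Series:
        """Number of individuals positive for each taxon."""
        return self.incidence.sum(axis=0)

    def to_tsv(self, path) -> None:
        pd.concat([self.meta, self.incidence], axis=1).to_csv(path, sep="\t", index_label="individual_id")

    @classmethod
    def from_tsv(cls, path) -> "DietMatrix":
        df = pd.read_csv(path, sep="\t", index_col="individual_id")
        meta = df[list(META_COLUMNS)]
        incidence = df.drop(columns=list(META_COLUMNS)).astype(int)
        return cls(incidence, meta)


def build_diet_matrix(
    detections: pd.DataFrame,
    rank_map: Mapping[str, str],
    metadata: pd.DataFrame,
    species_map: Mapping[str, str] | None = None,
) -> DietMatrix:
    """Build the binary diet matrix from per-individual detections.

    ``detections`` needs columns individual_id, taxon and status (as
    produced by :func:`dietlink.seqproc.detections_table`) or just
    individual_id and taxon for ground-truth input.  ``rank_map``
    merges assigned taxa to the taxonomic level of the prey-availability
    (kick-sample) data; every assigned taxon must be mapped.
    Contaminant and no-match detections are dropped, as are detections
    of the individual's own species (cannibalism is not resolvable);
    duplicates collapse to a single positive.  ``species_map``
    optionally translates each predator species to its analysis-level
    taxon for the own-species exclusion (defaults to ``rank_map`` where
    applicable, else identity).
    """
    if "status" in detections.columns:
        detections = detections[detections["status"] == "assigned"]
    detections = detections.dropna(subset=["taxon"])
    unmapped = sorted(set(detections["taxon"]) - set(rank_map))
    if unmapped:
        raise KeyError(f"taxa missing from rank_map: {', '.join(unmapped)}")
    missing_meta = sorted(set(detections["individual_id"]) - set(metadata.index))
    if missing_meta:
        raise KeyError(f"individuals missing from metadata: {', '.join(missing_meta)}")

    def own_taxon(species: str) -> str:
        if species_map and species in species_map:
            return species_map[species]
        return rank_map.get(species, species)

    taxa = sorted(set(rank_map.values()))
    incidence = pd.DataFrame(0, index=metadata.index, columns=taxa, dtype=int)
    for _, row in detections.iterrows():
        ind = row["individual_id"]
        mapped = rank_map[row["taxon"]]
        if mapped == own_taxon(metadata.loc[ind, "predator_species"]):
            continue
        incidence.loc[ind, mapped] = 1
    incidence = incidence.loc[:, incidence.sum(axis=0) > 0]
    return DietMatrix(incidence=incidence, meta=metadata[list(META_COLUMNS)].copy())


def mean_prey_per_individual(matrix: DietMatrix, **stratum) -> float:
    """Mean number of prey taxa detected per individual in a stratum."""
    sub = matrix.subset(**stratum) if stratum else matrix
    if sub.incidence.empty:
        raise ValueError("empty stratum")
    return float(sub.incidence.sum(axis=1).mean())


def utilization_vector(matrix: DietMatrix, **stratum) -> pd.Series:
    """Proportion of positive detections per taxon within a stratum.

    p_t = (individuals positive for t) / (total positives across taxa);
    sums to 1 whenever there is at least one positive.
    """
    sub = matrix.subset(**stratum) if stratum else matrix
    pos = sub.positives().astype(float)
    total = pos.sum()
    if total == 0:
        raise ValueError("no positive detections in stratum")
    return pos / total


def levins_breadth(p: pd.Series | Sequence[float], n_available: int) -> float:
    """Levins' standardized niche breadth B_A = (1/sum(p^2) - 1)/(n - 1).

    ``n_available`` is the number of potential prey taxa (those present
    in the availability data for the stratum).  B_A is 0 for complete
    specialisation on one taxon and 1 for uniform use of all available
    taxa.
    """
    p = np.asarray(p, dtype=float)
    if n_available < 2:
        raise ValueError("n_available must be >= 2")
    total = p.sum()
    if total <= 0:
        raise ValueError("utilization vector is all zero")
    if not np.isclose(total, 1.0):
        raise ValueError("utilization vector must sum to 1")
    b = 1.0 / np.square(p).sum()
    return float((b - 1.0) / (n_available - 1))


def pianka_overlap(p_j: pd.Series, p_k: pd.Series) -> float:
    """Pianka's symmetric niche overlap O_jk in [0, 1].

    O_jk = sum(p_ij p_ik) / sqrt(sum(p_ij^2) sum(p_ik^2)) over a common
    taxon support (vectors are aligned by index when given as Series).
    """
    if isinstance(p_j, pd.Series) and isinstance(p_k, pd.Series):
        support = p_j.index.union(p_k.index)
        a = p_j.reindex(support, fill_value=0.0).to_numpy(dtype=float)
        b = p_k.reindex(support, fill_value=0.0).to_numpy(dtype=float)
    else:
        a = np.asarray(p_j, dtype=float)
        b = np.asarray(p_k, dtype=float)
        if a.shape != b.shape:
            raise ValueError("utilization vectors must share a taxon support")
    denom = np.sqrt(np.square(a).sum() * np.square(b).sum())
    if denom == 0:
        raise ValueError("utilization vector is all zero")
    return float(np.clip(a @ b / denom, 0.0, 1.0))


def selection_strength(obs: pd.Series | Mapping[str, float], exp: pd.Series | Mapping[str, float]) -> float:
    """Scalar selection strength S in [0, 1].

    S = sum_t |o_t - e_t| / (sum_t o_t + sum_t e_t), where o_t is the
    observed number of individuals positive for taxon t and e_t the
    null-model expectation.  S = 0 iff observed equals expected for
    every taxon; S = 1 iff the observed and expected supports are
    disjoint.  The combined denominator is what makes both stated
    bounds exact (see the package methods notes).
    """
    o = pd.Series(obs, dtype=float)
    e = pd.Series(exp, dtype=float)
    if set(o.index) != set(e.index):
        raise ValueError("observed and expected must cover the same taxa")
    e = e.reindex(o.index)
    if (o < 0).any() or (e < 0).any():
        raise ValueError("counts must be nonnegative")
    denom = o.sum() + e.sum()
    if denom == 0:
        raise ValueError("observed and expected are both all zero")
    return float((o - e).abs().sum() / denom)


def niche_statistics(
    matrix: DietMatrix,
    abundance: pd.DataFrame | None = None,
    by: Sequence[str] = ("predator_species",),
) -> pd.DataFrame:
    """Tidy per-stratum niche summaries.

    For each stratum defined by the metadata columns in ``by``:
    number of individuals, mean prey per individual, and (when
    ``abundance`` is given, site-season x taxon counts) Levins' B_A
    with n_available = taxa with nonzero abundance in the stratum's
    sites (all sites when stratification does not involve site).
    """
    rows = []
    groups = matrix.meta.groupby(list(by), observed=True).groups
    for key, idx in groups.items():
        key_tuple = key if isinstance(key, tuple) else (key,)
        sub = DietMatrix(matrix.incidence.loc[idx], matrix.meta.loc[idx])
        row = dict(zip(by, key_tuple))
        row["n_individuals"] = len(idx)
        row["mean_prey_per_individual"] = mean_prey_per_individual(sub)
        if abundance is not None and sub.positives().sum() > 0:
            if "site_id" in by:
                site = row["site_id"]
                avail = abundance.xs(site, level="site_id") if isinstance(abundance.index, pd.MultiIndex) else abundance.loc[[site]]
            else:
                avail = abundance
            n_available = int((avail.sum(axis=0) > 0).sum())
            if n_available >= 2:
                row["levins_ba"] = levins_breadth(utilization_vector(sub), n_available)
        rows.append(row)
    return pd.DataFrame(rows)
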