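"""Alignment input, haplotype collapsing, and pairwise-difference matrices.

Sequences are mitochondrial fragments aligned to a common length; individuals
carrying identical sequences share a haplotype.  Distances between haplotypes
are raw site differences with pairwise deletion of gap/ambiguous positions:
a site contributes to d_ij only when both sequences carry an unambiguous base
(A, C, G or T) at that site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN-")
# IUPAC ambiguity codes other than N are demoted to N (with a warning).
_IUPAC_AMBIG = set("RYSWKMBDHV")

#: integer encoding used internally: A,C,G,T -> 0..3; gap/N/ambiguous -> 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}


class RaggedAlignmentError(ValueError):
    """A record's length differs from the rest of the alignment."""


class UnknownPopulationError(KeyError):
    """A sequence record's id has no entry in the population metadata."""


@dataclass
class PopulationMeta:
    """Sampling-site metadata for one population."""

    population: str
    locality: str = ""
    lineage: str = ""
    lat: float = float("nan")
    lon: float = float("nan")
    n: int = 0


@dataclass
class Alignment:
    """A rectangular nucleotide alignment with per-individual population labels."""

    ids: list[str]
    populations: list[str]
    matrix: np.ndarray  # (n_records, L) uint8, encoding per _CODE
    meta: pd.DataFrame | None = None  # one row per individual (id-indexed)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        inv = np.array(list("ACGTN"))
        return "".join(inv[self.matrix[i]])


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with a haplotype x population count matrix."""

    haplotypes: dict[str, np.ndarray]  # id -> encoded sequence (uint8)
    counts: pd.DataFrame  # index: haplotype id, columns: population id
    L: int = 0
    meta: pd.DataFrame | None = None  # per-population metadata, if known

    @property
    def K(self) -> int:
        return len(self.haplotypes)

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    def population_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def haplotype_counts(self, populations: list[str] | None = None) -> np.ndarray:
        """Total count per haplotype, optionally restricted to some populations."""
        sub = self.counts if populations is None else self.counts[populations]
        tot = sub.sum(axis=1).to_numpy()
        return tot

    @property
    def S_seg(self) -> int:
        return segregating_sites(list(self.haplotypes.values()))

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]], L: int = 0,
                    haplotypes: dict[str, np.ndarray] | None = None) -> "HaplotypeTable":
        """Build a table from nested counts ``{haplotype: {population: count}}``.

        When no sequences are supplied (published count tables), the
        ``haplotypes`` mapping holds empty arrays and sequence-based
        statistics are unavailable.
        """
        df = pd.DataFrame(counts).T.fillna(0).astype(int)
        if haplotypes is None:
            haplotypes = {h: np.empty(0, dtype=np.uint8) for h in df.index}
        return cls(haplotypes=haplotypes, counts=df, L=L)


def encode_sequence(seq: str, record_id: str = "?") -> np.ndarray:
    """Encode a nucleotide string to uint8 codes, demoting ambiguity codes to N."""
    s = seq.upper()
    out = np.empty(len(s), dtype=np.uint8)
    for i, ch in enumerate(s):
        code = _CODE.get(ch)
        if code is None:
            if ch in _IUPAC_AMBIG:
                logger.warning("record %s: ambiguity code %r at site %d treated as N",
                               record_id, ch, i)
                code = 4
            else:
                raise ValueError(f"record {record_id}: invalid character {ch!r} at site {i}")
        out[i] = code
    return out


def read_population_meta(path) -> pd.DataFrame:
    """Read a tab-separated metadata file (individual_id, population_id, lineage, lat, lon)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population_id": str})
    required = {"individual_id", "population_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual id in metadata: {dup}")
    return df.set_index("individual_id")


def read_alignment(path, meta) -> Alignment:
    """Read a FASTA alignment and attach population labels from a metadata table.

    ``meta`` may be a path to a tab-separated file or a DataFrame indexed by
    individual id with at least a ``population_id`` column.
    """
    if not isinstance(meta, pd.DataFrame):
        meta = read_population_meta(meta)
    ids, pops, rows = [], [], []
    L = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if L is None:
            L = len(seq)
        elif len(seq) != L:
            raise RaggedAlignmentError(
                f"record {rec.id} has length {len(seq)}, expected {L}")
        if rec.id not in meta.index:
            raise UnknownPopulationError(
                f"record {rec.id} has no population assignment in metadata")
        ids.append(rec.id)
        pops.append(str(meta.loc[rec.id, "population_id"]))
        rows.append(encode_sequence(seq, rec.id))
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in alignment")
    unmatched = meta.index.difference(ids)
    if len(unmatched):
        logger.info("%d metadata individuals absent from alignment: %s",
                    len(unmatched), list(unmatched[:5]))
    return Alignment(ids=ids, populations=pops, matrix=np.vstack(rows),
                     meta=meta.loc[ids])


def segregating_sites(encoded: list[np.ndarray]) -> int:
    """Number of columns with more than one unambiguous base among sequences."""
    if not encoded or encoded[0].size == 0:
        return 0
    m = np.vstack(encoded)
    s = 0
    for col in m.T:
        bases = np.unique(col[col < 4])
        if bases.size > 1:
            s += 1
    return int(s)


def collapse_haplotypes(a: Alignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes (ids H1..HK by first appearance)."""
    if a.n == 0:
        raise ValueError("empty alignment")
    order: dict[bytes, str] = {}
    haplotypes: dict[str, np.ndarray] = {}
    assign: list[str] = []
    for i in range(a.n):
        key = a.matrix[i].tobytes()
        if key not in order:
            hid = f"H{len(order) + 1}"
            order[key] = hid
            haplotypes[hid] = a.matrix[i]
        assign.append(order[key])
    pops = sorted(set(a.populations), key=a.populations.index)
    counts = pd.DataFrame(0, index=list(haplotypes), columns=pops, dtype=int)
    for hid, pop in zip(assign, a.populations):
        counts.loc[hid, pop] += 1
    meta = None
    if a.meta is not None and "lineage" in a.meta.columns:
        meta = (a.meta.groupby("population_id")
                .agg(lineage=("lineage", "first"))
                .reindex(pops))
        for c in ("lat", "lon"):
            if c in a.meta.columns:
                meta[c] = a.meta.groupby("population_id")[c].first().reindex(pops)
    return HaplotypeTable(haplotypes=haplotypes, counts=counts, L=a.L, meta=meta)


def pairwise_differences(t: HaplotypeTable) -> pd.DataFrame:
    """K x K matrix of site differences between haplotypes (pairwise deletion).

    A site is compared only when both sequences have an unambiguous base
    there; gap or N in either sequence excludes the site for that pair.
    """
    ids = t.haplotype_ids
    if any(t.haplotypes[h].size == 0 for h in ids):
        raise ValueError("haplotype table carries no sequences; "
                         "distances cannot be computed")
    m = np.vstack([t.haplotypes[h] for h in ids])
    valid = m < 4
    k = len(ids)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        both = valid[i] & valid[i + 1:]
        diff = (m[i] != m[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    d = d + d.T
    return pd.DataFrame(d, index=ids, columns=ids)


def expand_individual_distances(t: HaplotypeTable, d: pd.DataFrame,
                                populations: list[str] | None = None
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual distance matrix and population labels for a scope.

    Returns ``(dist, pop_index)`` where ``dist[i, j]`` is the haplotype
    distance between individuals i and j and ``pop_index[i]`` indexes into
    the selected population list.
    """
    pops = populations if populations is not None else t.populations
    hap_idx: list[int] = []
    pop_idx: list[int] = []
    ids = t.haplotype_ids
    for pi, p in enumerate(pops):
        col = t.counts[p]
        for hi, h in enumerate(ids):
            c = int(col[h])
            hap_idx.extend([hi] * c)
            pop_idx.extend([pi] * c)
    hap_idx_a = np.asarray(hap_idx)
    dm = d.to_numpy()[np.ix_(hap_idx_a, hap_idx_a)]
    return dm, np.asarray(pop_idx)
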