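"""Domain types and text-format I/O for per-site base counts.

The atomic observation is a vector of (A, C, G, T) read counts for one
individual at one genomic site.  Counts enter either from a simple
tab-separated table, from samtools mpileup text, or from the package's own
simulator; ms-format haplotype output can be read to obtain true genotypes.

Coordinates are 1-based throughout (the pileup convention).
"""

from __future__ import annotations

import heapq
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transition pairs on the 4-base alphabet (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))

INGROUP_LABELS = ("H1", "H2", "H3", "H4")


class ParseError(ValueError):
    """Malformed input text (carries file line number when available)."""


class ConfigError(ValueError):
    """Inconsistent population / individual configuration."""


class UndefinedFrequencyError(ValueError):
    """An allele frequency was requested where no reads back it (n = 0)."""


@dataclass(frozen=True)
class IndividualSiteCounts:
    """Base counts (A,C,G,T) for one individual at one site."""

    chrom: str
    pos: int
    counts: np.ndarray  # shape (4,), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4,):
            raise ValueError("counts must be a 4-vector (A,C,G,T)")
        if (c < 0).any():
            raise ValueError(f"negative base count at {self.chrom}:{self.pos}")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        """Total sequencing depth at the site."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class SiteTable:
    """Aligned base counts for every configured individual at one site.

    ``counts[i]`` is the (A,C,G,T) vector of individual ``individuals[i]``;
    individuals without data at the site carry zeros.
    """

    chrom: str
    pos: int
    individuals: tuple[str, ...]
    counts: np.ndarray  # shape (n_individuals, 4)
    block: int | None = None

    def pooled(self, indices: Sequence[int]) -> np.ndarray:
        return self.counts[list(indices)].sum(axis=0)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes coded as the count of the focal allele in {0,1,2}.

    ``genotypes`` has shape (n_individuals, n_sites).  ``positions`` holds
    either integer coordinates or ms-style fractions of a region length.
    """

    genotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.size and not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotypes must lie in {0, 1, 2}")
        self.genotypes = g.astype(np.int8)
        self.positions = np.asarray(self.positions)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class PopulationConfig:
    """Assignment of individuals to the quartet H1..H4 (+ optional H5).

    ``error_trio`` optionally names the (T, R, O) individuals used for
    type-specific error estimation: T is error-affected, R error-free and O
    an outgroup.
    """

    populations: dict[str, list[str]]
    error_trio: dict[str, str] = field(default_factory=dict)
    block_size: int = 5_000_000

    def __post_init__(self) -> None:
        for label in INGROUP_LABELS:
            if not self.populations.get(label):
                raise ConfigError(f"population {label} must have at least one individual")
        seen: dict[str, str] = {}
        for pop, inds in self.populations.items():
            for ind in inds:
                if ind in seen:
                    raise ConfigError(
                        f"individual {ind!r} assigned to both {seen[ind]} and {pop}"
                    )
                seen[ind] = pop
        bad = set(self.error_trio) - {"T", "R", "O"}
        if bad:
            raise ConfigError(f"unknown error-trio roles: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        """All individuals in population order (H1, H2, H3, H4, H5, ...)."""
        order = [k for k in ("H1", "H2", "H3", "H4", "H5") if k in self.populations]
        order += [k for k in self.populations if k not in order]
        return [ind for pop in order for ind in self.populations[pop]]

    def indices(self, individuals: Sequence[str]) -> dict[str, list[int]]:
        """Map each population to column indices in an individual list."""
        where = {ind: i for i, ind in enumerate(individuals)}
        out = {}
        for pop, inds in self.populations.items():
            missing = [i for i in inds if i not in where]
            if missing:
                raise ConfigError(f"individuals {missing} of {pop} absent from data")
            out[pop] = [where[i] for i in inds]
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationConfig":
        pops = {str(k): [str(v) for v in vals] for k, vals in dict(d["populations"]).items()}
        trio = {str(k): str(v) for k, v in dict(d.get("error_trio") or {}).items()}
        return cls(populations=pops, error_trio=trio, block_size=int(d.get("block_size", 5_000_000)))

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        doc = {"populations": self.populations, "block_size": self.block_size}
        if self.error_trio:
            doc["error_trio"] = self.error_trio
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class CountData:
    """Dense site-major container: counts[s, i, :] = base counts of individual i."""

    individuals: tuple[str, ...]
    chrom: np.ndarray  # (S,) str
    pos: np.ndarray  # (S,) int
    counts: np.ndarray  # (S, I, 4) int

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_site_tables(cls, tables: Iterable[SiteTable]) -> "CountData":
        tables = list(tables)
        if not tables:
            return cls((), np.array([], dtype=str), np.array([], dtype=np.int64),
                       np.zeros((0, 0, 4), dtype=np.int64))
        inds = tables[0].individuals
        for t in tables:
            if t.individuals != inds:
                raise ValueError("site tables carry inconsistent individual sets")
        return cls(
            individuals=inds,
            chrom=np.array([t.chrom for t in tables]),
            pos=np.array([t.pos for t in tables], dtype=np.int64),
            counts=np.stack([t.counts for t in tables]).astype(np.int64),
        )

    def site_tables(self) -> Iterator[SiteTable]:
        for s in range(self.n_sites):
            yield SiteTable(str(self.chrom[s]), int(self.pos[s]), self.individuals,
                            self.counts[s])

    def block_index(self, block_size: int) -> np.ndarray:
        """Block labels: blocks tile each chromosome from position 1."""
        per_chrom = (self.pos - 1) // block_size
        # offset blocks so labels are unique across chromosomes
        _, chrom_rank = np.unique(self.chrom, return_inverse=True)
        return chrom_rank * (int(per_chrom.max(initial=0)) + 1) + per_chrom


# ---------------------------------------------------------------------------
# count TSV
# ---------------------------------------------------------------------------

COUNT_TSV_COLUMNS = ("chrom", "pos", "individual", "nA", "nC", "nG", "nT")


def read_count_tsv(path, individuals: Sequence[str] | None = None) -> Iterator[SiteTable]:
    """Stream SiteTable records from a long-form count TSV.

    Columns: chrom, pos, individual, nA, nC, nG, nT.  Rows for a common
    (chrom, pos) must be contiguous; individuals absent at a site get zero
    counts.  When ``individuals`` is given, the table columns follow that
    order and unknown IDs raise :class:`ConfigError`.
    """
    with open(path) as fh:
        yield from _read_count_rows(fh, individuals)


def _read_count_rows(fh, individuals):
    known = list(individuals) if individuals is not None else None
    where = {ind: i for i, ind in enumerate(known)} if known is not None else None
    header = None
    current_key = None
    current: dict[str, np.ndarray] = {}
    order_seen: list[str] = []

    def flush():
        nonlocal current
        if current_key is None:
            return None
        inds = tuple(known) if known is not None else tuple(order_seen)
        counts = np.zeros((len(inds), 4), dtype=np.int64)
        for ind, c in current.items():
            idx = where[ind] if where is not None else order_seen.index(ind)
            counts[idx] = c
        table = SiteTable(current_key[0], current_key[1], inds, counts)
        current = {}
        return table

    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if header is None and fields[0] == "chrom":
            header = fields
            if tuple(header) != COUNT_TSV_COLUMNS:
                raise ParseError(f"line {lineno}: unexpected header {header}")
            continue
        if len(fields) != 7:
            raise ParseError(f"line {lineno}: expected 7 fields, got {len(fields)}")
        chrom, pos_s, ind = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
            c = np.array([int(x) for x in fields[3:7]], dtype=np.int64)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer field ({exc})") from None
        if (c < 0).any():
            raise ParseError(f"line {lineno}: negative base count")
        if known is not None and ind not in where:
            raise ConfigError(f"line {lineno}: unknown individual {ind!r}")
        key = (chrom, pos)
        if key != current_key:
            table = flush()
            if table is not None:
                yield table
            current_key = key
        if known is None and ind not in order_seen:
            order_seen.append(ind)
        current[ind] = c
    table = flush()
    if table is not None:
        yield table


def write_count_tsv(data: CountData | Iterable[SiteTable], path) -> None:
    """Write counts in the long-form TSV dialect read by :func:`read_count_tsv`."""
    tables = data.site_tables() if isinstance(data, CountData) else data
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_TSV_COLUMNS) + "\n")
        for t in tables:
            for ind, c in zip(t.individuals, t.counts):
                if c.sum() == 0:
                    continue
                fh.write(f"{t.chrom}\t{t.pos}\t{ind}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n")


# ---------------------------------------------------------------------------
# samtools mpileup text
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _decode_pileup_bases(bases: str, quals: str, ref: str, min_q: int) -> np.ndarray:
    """Decode one sample's pileup base string into (A,C,G,T) counts.

    Start marks (``^`` + mapping-quality char), end marks (``$``), indel
    spans (``+n``/``-n`` plus n characters) and deletion placeholders
    (``*``, ``>``, ``<``) are skipped; reference shorthands ``.``/``,`` map
    to the reference base.  Bases with Phred quality below ``min_q`` are
    excluded.
    """
    counts = np.zeros(4, dtype=np.int64)
    ref_idx = BASE_INDEX.get(ref.upper(), -1)
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret + mapping quality character, no base consumed
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ParseError(f"malformed indel spec in pileup bases {bases!r}")
            length = int(m.group(1))
            i = m.end() + length
            continue
        # every remaining symbol consumes one quality character
        if qi >= len(quals):
            raise ParseError("pileup base/quality strings out of register")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if ch in "*><Nn":
            continue
        if q < min_q:
            continue
        if ch in ".,":
            if ref_idx >= 0:
                counts[ref_idx] += 1
            continue
        idx = BASE_INDEX.get(ch.upper())
        if idx is not None:
            counts[idx] += 1
    return counts


def parse_mpileup(stream: Iterable[str] | io.TextIOBase, individuals: Sequence[str],
                  min_base_quality: int = 20) -> Iterator[SiteTable]:
    """Parse multi-sample samtools mpileup text into SiteTable records.

    One (depth, bases, qualities) column triplet is expected per individual,
    in the order given.  Sites whose reference base is ``N`` and that carry
    only reference-shorthand observations are dropped with a warning —
    their base identity is unknowable.  The mapping-quality filter of
    upstream pipelines cannot be applied here (pileup text has no per-read
    mapping quality); apply it when generating the pileup.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    n_ind = len(individuals)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3 + 3 * n_ind:
            raise ParseError(
                f"line {lineno}: expected {3 + 3 * n_ind} columns for "
                f"{n_ind} individuals, got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
        counts = np.zeros((n_ind, 4), dtype=np.int64)
        ref_only = True
        for k in range(n_ind):
            depth_s, bases, quals = fields[3 + 3 * k: 6 + 3 * k]
            if bases.strip("*") and any(c not in ".,$^" for c in bases):
                ref_only = False
            counts[k] = _decode_pileup_bases(bases, quals, ref, min_base_quality)
            if counts[k].sum() > int(depth_s):
                raise ParseError(f"line {lineno}: decoded more bases than the depth column")
        if ref.upper() == "N":
            if counts.sum() == 0 and ref_only:
                warnings.warn(f"line {lineno}: dropping site with 'N' reference")
                continue
            if counts.sum() == 0:
                continue
        yield SiteTable(chrom, pos, tuple(individuals), counts)


# ---------------------------------------------------------------------------
# ms / msms text output
# ---------------------------------------------------------------------------

def read_ms(stream: Iterable[str] | io.TextIOBase, ploidy: int = 2,
            region_length: int | None = None) -> list[GenotypeMatrix]:
    """Read ms-format replicates into genotype matrices.

    Consecutive groups of ``ploidy`` haplotype rows are summed into
    genotypes.  When ``region_length`` is given, fractional positions are
    mapped to 1-based integer coordinates by ``floor(pos * L) + 1`` with
    duplicate coordinates dropped (first kept).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = iter(stream)
    replicates: list[GenotypeMatrix] = []
    current_haps: list[str] | None = None
    positions: np.ndarray | None = None
    segsites = None

    def flush():
        nonlocal current_haps, positions, segsites
        if current_haps is None:
            return
        if segsites == 0:
            replicates.append(GenotypeMatrix(np.zeros((0, 0)), np.array([])))
        else:
            if len(current_haps) % ploidy:
                raise ParseError(
                    f"{len(current_haps)} haplotype rows not divisible by ploidy {ploidy}"
                )
            hap = np.array([[int(c) for c in row] for row in current_haps], dtype=np.int8)
            geno = hap.reshape(len(current_haps) // ploidy, ploidy, -1).sum(axis=1)
            pos = positions
            if region_length is not None:
                ipos = np.floor(pos * region_length).astype(np.int64) + 1
                keep = np.concatenate([[True], np.diff(ipos) > 0])
                geno, pos = geno[:, keep], ipos[keep]
            replicates.append(GenotypeMatrix(geno, pos))
        current_haps, positions, segsites = None, None, None

    for raw in lines:
        line = raw.strip()
        if line.startswith("//"):
            flush()
            current_haps = []
        elif line.startswith("segsites:"):
            segsites = int(line.split(":")[1])
        elif line.startswith("positions:"):
            positions = np.array([float(x) for x in line.split(":")[1].split()])
            if positions.size and (positions.min() < 0 or positions.max() > 1):
                raise ParseError("ms positions must lie in [0, 1]")
        elif current_haps is not None and line and set(line) <= {"0", "1"}:
            current_haps.append(line)
    flush()
    return replicates


# ---------------------------------------------------------------------------
# site intersection
# ---------------------------------------------------------------------------

def merge_individual_streams(
    streams: Mapping[str, Iterable[IndividualSiteCounts]],
    individuals: Sequence[str] | None = None,
) -> Iterator[SiteTable]:
    """Merge coordinate-sorted per-individual count streams into SiteTables.

    Chromosome order is taken from first appearance and must be consistent
    across streams; an out-of-order coordinate raises :class:`ParseError`
    naming the offending site.
    """
    inds = tuple(individuals if individuals is not None else streams.keys())
    chrom_rank: dict[str, int] = {}

    def rank(chrom: str) -> int:
        if chrom not in chrom_rank:
            chrom_rank[chrom] = len(chrom_rank)
        return chrom_rank[chrom]

    heap: list = []
    iters = {ind: iter(streams[ind]) for ind in inds}
    last_seen: dict[str, tuple[int, int]] = {}

    def push(ind):
        rec = next(iters[ind], None)
        if rec is None:
            return
        key = (rank(rec.chrom), rec.pos)
        if ind in last_seen and key <= last_seen[ind]:
            raise ParseError(f"unsorted input for {ind} at {rec.chrom}:{rec.pos}")
        last_seen[ind] = key
        heapq.heappush(heap, (key, ind, rec))

    for ind in inds:
        push(ind)
    while heap:
        key = heap[0][0]
        counts = np.zeros((len(inds), 4), dtype=np.int64)
        chrom, pos = None, None
        while heap and heap[0][0] == key:
            _, ind, rec = heapq.heappop(heap)
            counts[inds.index(ind)] = rec.counts
            chrom, pos = rec.chrom, rec.pos
            push(ind)
        yield SiteTable(chrom, pos, inds, counts)


def intersect_sites(
    tables: Iterable[SiteTable],
    config: PopulationConfig,
    min_pooled_depth: int = 1,
) -> Iterator[SiteTable]:
    """Keep only sites with pooled depth >= threshold in each of H1..H4.

    Individuals with no reads at a retained site stay present with zero
    counts; their weight in frequency estimation is zero.
    """
    idx = None
    for t in tables:
        if idx is None:
            idx = {p: [t.individuals.index(i) for i in config.populations[p]]
                   for p in INGROUP_LABELS}
        if all(t.pooled(idx[p]).sum() >= min_pooled_depth for p in INGROUP_LABELS):
            yield t
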