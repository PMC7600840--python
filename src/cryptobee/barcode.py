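"""COI barcode analysis at desk scale.

The species identities behind the morphometrics are confirmed with a
short (~150 bp) diagnostic fragment of the mitochondrial COI barcode.
This module collapses aligned, equal-length sequences into haplotypes,
computes pairwise and group-wise percent identity, and links haplotypes
into a minimum-spanning forest whose edges carry base-pair differences,
cut at a connection limit — a deliberately simple stand-in for the
statistical-parsimony network of the classic TCS approach (which the
connection limit parameterises; the full coalescent probability
calculation is not re-derived here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ACGT = frozenset("ACGT")

#: default statistical-parsimony connection limit (substitution steps)
#: typical of ~150 bp fragments at a 95% parsimony probability
DEFAULT_CONNECTION_LIMIT = 10


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class Haplotype:
    name: str
    sequence: str
    members: tuple[str, ...]
    species: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[Haplotype, ...]
    edges: tuple[tuple[str, str, int], ...]  # (name_a, name_b, n_diff)
    connection_limit: int

    def components(self) -> list[set[str]]:
        parent = {h.name: h.name for h in self.nodes}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b, _ in self.edges:
            parent[find(a)] = find(b)
        comp: dict[str, set[str]] = {}
        for h in self.nodes:
            comp.setdefault(find(h.name), set()).add(h.name)
        return list(comp.values())


def read_fasta(path) -> list[SequenceRecord]:
    """Load a FASTA file; ``species=<label>`` tokens in descriptions are parsed."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        species = "unknown"
        for token in rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        records.append(SequenceRecord(id=rec.id, species=species, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        [_BioSeqRecord(Seq(r.sequence), id=r.id, description=f"species={r.species}")
         for r in records],
        str(path), "fasta",
    )


def _check_aligned(records: Sequence[SequenceRecord]) -> int:
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not equal length: {sorted(lengths)}")
    return lengths.pop()


def collapse_haplotypes(records: Sequence[SequenceRecord]) -> list[Haplotype]:
    """One haplotype per distinct sequence, named H001, H002, ... in
    order of each haplotype's first member."""
    _check_aligned(records)
    groups: dict[str, list[SequenceRecord]] = {}
    for r in records:
        groups.setdefault(r.sequence, []).append(r)
    out = []
    for i, (seq, members) in enumerate(groups.items(), start=1):
        species: dict[str, int] = {}
        for m in members:
            species[m.species] = species.get(m.species, 0) + 1
        out.append(Haplotype(
            name=f"H{i:03d}", sequence=seq,
            members=tuple(m.id for m in members), species=species,
        ))
    return out


def _diff_count(a: str, b: str) -> tuple[int, int]:
    """(mismatches, comparable sites); sites with non-ACGT in either
    sequence are excluded from both counts."""
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    acgt = np.array([c.encode() for c in "ACGT"], dtype="S1")
    ok = np.isin(aa, acgt) & np.isin(bb, acgt)
    return int(np.sum((aa != bb) & ok)), int(ok.sum())


def percent_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Fraction of comparable (ACGT-in-both) sites at which a and b agree."""
    sa = a.sequence if isinstance(a, SequenceRecord) else a.upper()
    sb = b.sequence if isinstance(b, SequenceRecord) else b.upper()
    if len(sa) != len(sb):
        raise ValueError("sequences must be equal length (pre-aligned, ungapped)")
    diff, comparable = _diff_count(sa, sb)
    if comparable == 0:
        raise ValueError("no comparable ACGT sites")
    return 1.0 - diff / comparable


def group_similarity(records: Sequence[SequenceRecord]):
    """Mean pairwise identity within and between species.

    Returns a symmetric species x species DataFrame; the diagonal is the
    mean over unordered within-species pairs (NaN for singleton species),
    off-diagonals average all cross-species pairs.
    """
    import pandas as pd

    _check_aligned(records)
    species = sorted({r.species for r in records})
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    by_sp = {s: [r for r in records if r.species == s] for s in species}
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    for i, s1 in enumerate(species):
        for s2 in species[i:]:
            if s1 == s2:
                grp = by_sp[s1]
                if len(grp) < 2:
                    continue
                vals = [percent_identity(grp[a], grp[b])
                        for a in range(len(grp)) for b in range(a + 1, len(grp))]
            else:
                vals = [percent_identity(x, y) for x in by_sp[s1] for y in by_sp[s2]]
            mat.loc[s1, s2] = mat.loc[s2, s1] = float(np.mean(vals))
    return mat


def build_network(haplotypes: Sequence[Haplotype],
                  connection_limit: int = DEFAULT_CONNECTION_LIMIT) -> HaplotypeNetwork:
    """Minimum-spanning forest over haplotypes under base-pair distance.

    Kruskal with deterministic tie-breaking by (n_diff, name_a, name_b);
    candidate edges with more than ``connection_limit`` differences are
    never used, so over-divergent groups stay disconnected — mirroring
    how a parsimony connection limit splits species into separate
    subnetworks.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    names = [h.name for h in haplotypes]
    candidates = []
    for i in range(len(haplotypes)):
        for j in range(i + 1, len(haplotypes)):
            d, _ = _diff_count(haplotypes[i].sequence, haplotypes[j].sequence)
            if d <= connection_limit:
                a, b = sorted((names[i], names[j]))
                candidates.append((d, a, b))
    candidates.sort()

    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = []
    for d, a, b in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, d))
    return HaplotypeNetwork(nodes=tuple(haplotypes), edges=tuple(edges),
                            connection_limit=connection_limit)
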