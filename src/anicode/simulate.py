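"""Synthetic genome clades with a known mutation history.

Genomes are evolved down a rooted tree from a random ancestor. Each
branch carries a per-site substitution probability; a site that
mutates takes one of the three alternative bases uniformly (the
simplest symmetric model — the goal is a controllable divergence dial
for testing classification machinery, not evolutionary realism).
Optional extras emulate the two complications the code system has to
cope with: horizontal transfer (a divergent donor segment spliced into
one leaf, the situation the core-genome filter exists for) and short
indels (1-10 bp).

Every mutation is recorded in a :class:`MutationLedger`; replaying the
ledger on the root reproduces each leaf byte-for-byte, which makes the
ledger an independent oracle for ANI-recovery tests. The closed-form
expected identity between two leaves under the substitution model is
``25 + 75 * prod(1 - 4*p_i/3)`` percent over the branches on the
connecting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .seqio import GenomeRecord, genome_from_contigs, write_genome

__all__ = [
    "CladeSpec",
    "HgtEvent",
    "MutationLedger",
    "simulate_clade",
    "expected_identity",
    "balanced_clade_newick",
    "write_clade",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class HgtEvent:
    """Splice a divergent segment into one leaf (same length, so vertical
    coordinates outside the segment are untouched)."""

    recipient: str
    segment_length: int
    donor_rate: float
    start: Optional[int] = None   # None: drawn uniformly


@dataclass(frozen=True)
class CladeSpec:
    """Specification of one simulated clade.

    root_length   ancestor length in bp (>= 10 fragment lengths
                  recommended so per-fragment statistics are stable).
    newick        rooted tree; branch lengths are per-site substitution
                  probabilities in [0, 1).
    hgt_events    optional horizontal-transfer events.
    indel_rate    per-site probability of an indel on each terminal
                  branch (short, 1-10 bp; default off).
    seed          reproducibility: same spec + seed => same genomes.
    """

    root_length: int
    newick: str
    hgt_events: Tuple[HgtEvent, ...] = ()
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        if not (0 <= self.indel_rate < 1):
            raise ValueError("indel_rate must be in [0, 1)")
        for ev in self.hgt_events:
            if not (0 <= ev.donor_rate < 1):
                raise ValueError("hgt donor_rate must be in [0, 1)")

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(data=self.newick, schema="newick")
        for edge in t.preorder_edge_iter():
            p = edge.length or 0.0
            if not (0 <= p < 1):
                raise ValueError(f"branch probability {p} outside [0, 1)")
        return t


@dataclass
class MutationLedger:
    """Complete record of how each leaf was derived from the root.

    Events per leaf, in application order:
      ("sub", pos, old_base, new_base)   substitutions along the root
                                         path, root-to-leaf order
      ("ins", pos, inserted_seq)         insertion before pos
      ("del", pos, length)               deletion at pos
      ("hgt", start, donor_seq)          segment replacement
    Bases are ACGT characters; positions are valid at application time.
    """

    root_seq: str
    events: Dict[str, List[tuple]] = field(default_factory=dict)

    def replay(self, leaf: str, include_hgt: bool = True,
               include_indels: bool = True) -> str:
        """Rebuild a leaf sequence from the root. Excluding HGT events
        yields the purely vertically inherited version of the leaf."""
        if leaf not in self.events:
            raise KeyError(f"unknown leaf {leaf!r}")
        seq = list(self.root_seq)
        for ev in self.events[leaf]:
            kind = ev[0]
            if kind == "sub":
                _, pos, old, new = ev
                assert seq[pos] == old
                seq[pos] = new
            elif kind == "ins":
                if include_indels:
                    seq[ev[1]:ev[1]] = list(ev[2])
            elif kind == "del":
                if include_indels:
                    del seq[ev[1]:ev[1] + ev[2]]
            elif kind == "hgt":
                if include_hgt:
                    _, start, donor = ev
                    seq[start:start + len(donor)] = list(donor)
            else:  # pragma: no cover - defensive
                raise ValueError(f"unknown event kind {kind!r}")
        return "".join(seq)

    def hgt_regions(self, leaf: str) -> List[Tuple[int, int]]:
        """[start, end) intervals replaced by horizontal transfer."""
        return [(ev[1], ev[1] + len(ev[2]))
                for ev in self.events.get(leaf, []) if ev[0] == "hgt"]


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator
            ) -> Tuple[np.ndarray, List[tuple]]:
    """One round of per-site substitution at probability p."""
    out = seq.copy()
    if p <= 0:
        return out, []
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size == 0:
        return out, []
    shift = rng.integers(1, 4, size=hit.size)
    old = out[hit]
    new_idx = (np.searchsorted(_BASES, old) + shift) % 4
    out[hit] = _BASES[new_idx]
    events = [("sub", int(pos), chr(o), chr(_BASES[ni]))
              for pos, o, ni in zip(hit, old, new_idx)]
    return out, events


def simulate_clade(spec: CladeSpec) -> Tuple[List[GenomeRecord], MutationLedger]:
    """Evolve the clade and return (one GenomeRecord per leaf, ledger).

    Leaves are returned in the tree's leaf order; each genome has a
    single contig named after its leaf. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree()
    root_arr = _BASES[rng.integers(0, 4, size=spec.root_length)]
    root_seq = root_arr.tobytes().decode("ascii")
    ledger = MutationLedger(root_seq=root_seq)

    seqs: Dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
    path_events: Dict[int, List[tuple]] = {id(tree.seed_node): []}
    genomes: List[GenomeRecord] = []

    hgt_by_leaf: Dict[str, List[HgtEvent]] = {}
    for ev in spec.hgt_events:
        hgt_by_leaf.setdefault(ev.recipient, []).append(ev)

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        p = node.edge.length or 0.0
        seq, events = _mutate(parent_seq, p, rng)
        seqs[id(node)] = seq
        path_events[id(node)] = path_events[id(node.parent_node)] + events
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(genomes)}"
            label = label.replace(" ", "_")
            leaf_events = list(path_events[id(node)])
            chars = list(seq.tobytes().decode("ascii"))
            # indels on the terminal branch only, so that substitution
            # coordinates along the path stay root-based
            if spec.indel_rate > 0:
                n_indels = rng.binomial(len(chars), spec.indel_rate)
                for _ in range(n_indels):
                    pos = int(rng.integers(0, len(chars)))
                    length = int(rng.integers(1, 11))
                    if rng.random() < 0.5:
                        ins = "".join(chr(b) for b in
                                      _BASES[rng.integers(0, 4, size=length)])
                        chars[pos:pos] = list(ins)
                        leaf_events.append(("ins", pos, ins))
                    else:
                        length = min(length, len(chars) - pos)
                        if length:
                            del chars[pos:pos + length]
                            leaf_events.append(("del", pos, length))
            for ev in hgt_by_leaf.get(label, []):
                if ev.segment_length > len(chars):
                    raise ValueError("HGT segment longer than the genome")
                start = (ev.start if ev.start is not None else
                         int(rng.integers(0, len(chars) - ev.segment_length + 1)))
                segment = np.frombuffer(
                    "".join(chars[start:start + ev.segment_length])
                    .encode("ascii"), dtype=np.uint8)
                donor_arr, _ = _mutate(segment, ev.donor_rate, rng)
                donor = donor_arr.tobytes().decode("ascii")
                chars[start:start + ev.segment_length] = list(donor)
                leaf_events.append(("hgt", start, donor))
            ledger.events[label] = leaf_events
            genomes.append(genome_from_contigs(label, [(label, "".join(chars))]))
    return genomes, ledger


def expected_identity(spec: CladeSpec, leaf_a: str, leaf_b: str) -> float:
    """Closed-form expected per-site identity (%) between two leaves.

    Under the one-round symmetric substitution model each branch has
    transition matrix (1-p) I + (p/3)(J - I), whose non-unit eigenvalue
    is 1 - 4p/3; composing along the path gives
    P(same base) = 1/4 + 3/4 * prod(1 - 4 p_i / 3).
    HGT and indels are outside this expectation.
    """
    if leaf_a == leaf_b:
        return 100.0
    tree = spec.tree()
    nodes = {}
    for leaf in tree.leaf_node_iter():
        label = (leaf.taxon.label if leaf.taxon else "").replace(" ", "_")
        nodes[label] = leaf
    for leaf in (leaf_a, leaf_b):
        if leaf not in nodes:
            raise KeyError(f"unknown leaf {leaf!r}")

    def ancestors(node):
        out = [node]
        while node.parent_node is not None:
            node = node.parent_node
            out.append(node)
        return out

    anc_a = ancestors(nodes[leaf_a])
    anc_b = ancestors(nodes[leaf_b])
    set_a = set(id(n) for n in anc_a)
    mrca = next(n for n in anc_b if id(n) in set_a)
    prod = 1.0
    for chain in (anc_a, anc_b):
        for node in chain:
            if node is mrca:
                break
            p = node.edge.length or 0.0
            prod *= 1.0 - 4.0 * p / 3.0
    return 100.0 * (0.25 + 0.75 * prod)


def balanced_clade_newick(tiers: Sequence[Tuple[int, float]],
                          prefix: str = "g") -> str:
    """Newick for a balanced multi-tier clade.

    ``tiers`` is outermost-first: ``[(3, 0.05), (2, 0.007), (2, 2.5e-4)]``
    gives 3 families x 2 genera x 2 strains = 12 leaves, with the given
    per-site substitution probability on every branch of that tier.
    Leaf names encode the path, e.g. ``g2.1.2``.
    """
    if not tiers:
        raise ValueError("need at least one tier")

    def build(level: int, path: str) -> str:
        n, p = tiers[level]
        parts = []
        for i in range(1, n + 1):
            child_path = f"{path}.{i}" if path else str(i)
            if level + 1 == len(tiers):
                parts.append(f"{prefix}{child_path}:{p:g}")
            else:
                parts.append(f"{build(level + 1, child_path)}:{p:g}")
        return "(" + ",".join(parts) + ")"

    return build(0, "") + ";"


def write_clade(genomes: Sequence[GenomeRecord], ledger: MutationLedger,
                spec: CladeSpec, outdir: str | Path) -> None:
    """Write one FASTA per leaf, the event ledger as TSV, and the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genome(g, outdir / f"{g.genome_id}.fasta")
    with open(outdir / "ledger.tsv", "w") as fh:
        fh.write("leaf\tkind\tfield1\tfield2\tfield3\n")
        for leaf, events in ledger.events.items():
            for ev in events:
                fields = [str(x) for x in ev[1:]] + [""] * (3 - len(ev[1:]))
                fh.write("\t".join([leaf, ev[0]] + fields) + "\n")
    with open(outdir / "spec.txt", "w") as fh:
        fh.write(f"root_length: {spec.root_length}\n")
        fh.write(f"newick: {spec.newick}\n")
        fh.write(f"indel_rate: {spec.indel_rate}\n")
        fh.write(f"seed: {spec.seed}\n")
        for ev in spec.hgt_events:
            fh.write(f"hgt: {ev.recipient} {ev.segment_length} "
                     f"{ev.donor_rate} {ev.start}\n")
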