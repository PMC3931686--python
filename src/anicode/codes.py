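"""Hierarchical genome codes and the growing code registry.

Every coded genome holds a vector of non-negative integers, one per
similarity threshold. The default table has 24 positions labelled A..X
with ANI thresholds rising from 60% to 99.9999%; sharing a position
means both genomes cleared that threshold relative to their assignment
anchors, so the further right two codes agree, the more similar the
organisms.

Assignment is sequential. The first genome registered gets 0 at every
position. Each later genome is compared against all registered genomes;
among subjects to which at least 20% of the query's fragments align,
the one with the highest ANI is the anchor. The code walk copies the
anchor's value at every position whose threshold the ANI strictly
exceeds; at the first position where it does not, a fresh value is
issued and all later positions become 0. Fresh values are numbered
within the sibling group — registered genomes whose codes agree with
the new code at every position to the left — so numbering restarts
inside each lineage. A query that aligns to nothing well enough (< 20%
aligned fragments, or no passed fragments at all) founds a new lineage:
fresh value at the first position, zeros elsewhere.

Codes are immutable once assigned; registering genome n+1 never touches
the codes of genomes 1..n. Two genomes whose ANI clears even the
deepest threshold legitimately share a full code — uniqueness is per
genome, not per code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .ani import AniConfig, PairwiseSimilarity, SimilarityCache
from .seqio import GenomeRecord, read_genome

__all__ = [
    "ThresholdTable",
    "DEFAULT_THRESHOLDS",
    "GenomeCode",
    "RegistryEntry",
    "CodeRegistry",
    "DuplicateGenomeError",
    "build_registry",
    "last_shared_position",
    "format_code",
    "parse_code",
    "CodeParseError",
]


class DuplicateGenomeError(ValueError):
    """A genome with the same content checksum is already registered."""

    def __init__(self, entry: "RegistryEntry") -> None:
        super().__init__(
            f"genome already registered as {entry.genome.genome_id!r} "
            f"with code {format_code(entry.code)}")
        self.entry = entry


class CodeParseError(ValueError):
    """Malformed code text; carries the token offset of the problem."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (token {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ThresholdTable:
    """Ordered (label, ANI threshold %) pairs with strictly rising thresholds."""

    positions: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("threshold table must not be empty")
        thr = [t for _, t in self.positions]
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if any(not (0 < t < 100) for t in thr):
            raise ValueError("thresholds must lie in (0, 100)")
        labels = [l for l, _ in self.positions]
        if len(set(labels)) != len(labels):
            raise ValueError("position labels must be unique")

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(l for l, _ in self.positions)

    @property
    def thresholds(self) -> Tuple[float, ...]:
        return tuple(t for _, t in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown position label {label!r}") from None

    def table_id(self) -> str:
        return "|".join(f"{l}:{t:g}" for l, t in self.positions)


#: The 24-position default: family-level 60% up to 99.9999% for
#: near-identical genomes; spacing tightens to the right because the
#: system's goal is high resolution among very similar organisms.
DEFAULT_THRESHOLDS = ThresholdTable(positions=(
    ("A", 60.0), ("B", 70.0), ("C", 80.0), ("D", 85.0), ("E", 90.0),
    ("F", 95.0), ("G", 98.0), ("H", 99.0), ("I", 99.5), ("J", 99.6),
    ("K", 99.7), ("L", 99.8), ("M", 99.9), ("N", 99.91), ("O", 99.92),
    ("P", 99.93), ("Q", 99.94), ("R", 99.95), ("S", 99.96), ("T", 99.97),
    ("U", 99.98), ("V", 99.99), ("W", 99.999), ("X", 99.9999),
))


@dataclass(frozen=True)
class GenomeCode:
    """Code values, one per threshold position; None marks an unshown
    position in a partial (projected) code."""

    values: Tuple[Optional[int], ...]
    table_ref: str = DEFAULT_THRESHOLDS.table_id()

    def __post_init__(self) -> None:
        for v in self.values:
            if v is not None and v < 0:
                raise ValueError("code values must be non-negative")

    @property
    def is_partial(self) -> bool:
        return any(v is None for v in self.values)


@dataclass(frozen=True)
class RegistryEntry:
    genome: GenomeRecord
    code: GenomeCode
    assigned_from: Optional[str]          # genome_id of the anchor
    ani_at_assignment: Optional[float]
    pct_aligned_at_assignment: Optional[float]
    assignment_index: int
    trusted: bool = True                  # False: new-lineage assignment


class CodeRegistry:
    """Ordered, append-only collection of coded genomes.

    Holds the threshold table and ANI configuration used for every
    assignment, plus a similarity cache so repeated registry builds
    over the same genomes (e.g. order-permutation studies) align each
    ordered pair only once.
    """

    def __init__(self,
                 thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                 ani_config: AniConfig = AniConfig(),
                 cache: Optional[SimilarityCache] = None) -> None:
        self.thresholds = thresholds
        self.ani_config = ani_config
        self.cache = cache or SimilarityCache()
        self.entries: List[RegistryEntry] = []
        self._by_checksum: Dict[str, RegistryEntry] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def entry_for(self, genome_id: str) -> RegistryEntry:
        for e in self.entries:
            if e.genome.genome_id == genome_id:
                return e
        raise KeyError(f"genome {genome_id!r} not in registry")

    # -- assignment ---------------------------------------------------------

    def register_first(self, genome: GenomeRecord) -> RegistryEntry:
        """Register the very first genome: 0 at all positions."""
        if self.entries:
            raise ValueError("registry is not empty; use assign_code")
        entry = RegistryEntry(
            genome=genome,
            code=GenomeCode(values=(0,) * len(self.thresholds),
                            table_ref=self.thresholds.table_id()),
            assigned_from=None,
            ani_at_assignment=None,
            pct_aligned_at_assignment=None,
            assignment_index=0,
        )
        self._append(entry)
        return entry

    def find_most_similar(self, query: GenomeRecord
                          ) -> Tuple[RegistryEntry, PairwiseSimilarity, bool]:
        """Most similar registered genome for a query.

        Subjects reaching the aligned-fragments trust cutoff take
        precedence; among them the highest ANI wins even if some
        below-cutoff subject shows a higher ANI. Without any such
        subject the globally highest ANI is returned untrusted. ANI
        ties go to the earlier-registered genome.
        """
        if not self.entries:
            raise ValueError("registry is empty; use register_first")
        cfg = self.ani_config
        sims = [(e, self.cache.similarity(query, e.genome, cfg))
                for e in self.entries]
        trusted_pool = [(e, s) for e, s in sims
                        if s.pct_aligned_fragments >= cfg.trust_min_pct_aligned
                        and s.ani_pct is not None]
        pool, trusted = (trusted_pool, True) if trusted_pool else (sims, False)
        best_e, best_s = max(
            pool,
            key=lambda es: (es[1].ani_pct if es[1].ani_pct is not None
                            else float("-inf"),
                            -es[0].assignment_index))
        return best_e, best_s, trusted

    def _fresh_value(self, prefix: Sequence[int], position: int) -> int:
        """Next number within the sibling group sharing ``prefix``.

        1 + max value at ``position`` among entries whose codes agree
        with ``prefix`` at every earlier position; 0 when the prefix is
        brand new (no sibling exists).
        """
        sib_values = [e.code.values[position] for e in self.entries
                      if tuple(e.code.values[:position]) == tuple(prefix)]
        return max(sib_values) + 1 if sib_values else 0

    def assign_code(self, query: GenomeRecord) -> RegistryEntry:
        """Assign the next genome its code from its most similar anchor.

        The threshold walk uses strict comparison: a genome whose ANI
        equals a cutoff exactly does not share that position. An ANI
        exceeding every threshold copies the anchor's full code.
        """
        if not self.entries:
            raise ValueError("registry is empty; use register_first")
        existing = self._by_checksum.get(query.checksum)
        if existing is not None:
            raise DuplicateGenomeError(existing)
        best, sim, trusted = self.find_most_similar(query)
        n = len(self.thresholds)
        if not trusted or sim.ani_pct is None:
            values = [self._fresh_value((), 0)] + [0] * (n - 1)
        else:
            values = []
            anchor = best.code.values
            for k, thr in enumerate(self.thresholds.thresholds):
                if sim.ani_pct > thr:
                    values.append(anchor[k])
                else:
                    values.append(self._fresh_value(values, k))
                    values.extend([0] * (n - k - 1))
                    break
        entry = RegistryEntry(
            genome=query,
            code=GenomeCode(values=tuple(values),
                            table_ref=self.thresholds.table_id()),
            assigned_from=best.genome.genome_id,
            ani_at_assignment=sim.ani_pct,
            pct_aligned_at_assignment=sim.pct_aligned_fragments,
            assignment_index=len(self.entries),
            trusted=trusted,
        )
        self._append(entry)
        return entry

    def register(self, genome: GenomeRecord) -> RegistryEntry:
        """register_first or assign_code depending on registry state."""
        if not self.entries:
            return self.register_first(genome)
        return self.assign_code(genome)

    def _append(self, entry: RegistryEntry) -> None:
        self.entries.append(entry)
        self._by_checksum[entry.genome.checksum] = entry

    # -- reporting and persistence -----------------------------------------

    def provenance_table(self) -> pd.DataFrame:
        """One row per genome: code, anchor, ANI%, % aligned fragments."""
        rows = []
        for e in self.entries:
            rows.append({
                "genome_id": e.genome.genome_id,
                "code": format_code(e.code),
                "assigned_from": e.assigned_from or "",
                "ani_pct": e.ani_at_assignment,
                "pct_aligned_fragments": e.pct_aligned_at_assignment,
                "trusted": e.trusted,
            })
        return pd.DataFrame(rows)

    def export_table(self, positions: Optional[Sequence[str]] = None
                     ) -> pd.DataFrame:
        """Code table with codes projected to a label subset (e.g. V..X)."""
        df = self.provenance_table()
        if positions is not None:
            df["code"] = [format_code(e.code, show_positions=positions)
                          for e in self.entries]
        return df

    def save(self, path: str | Path) -> None:
        """Write the registry as JSON-lines (one entry per line).

        The first line is a header with the threshold table and the ANI
        config digest, so extension runs can verify they use the same
        parameters.
        """
        with open(path, "w") as fh:
            header = {
                "kind": "anicode-registry",
                "thresholds": [[l, t] for l, t in self.thresholds.positions],
                "config": self.ani_config.__dict__,
                "config_digest": self.ani_config.digest(),
            }
            fh.write(json.dumps(header) + "\n")
            for e in self.entries:
                fh.write(json.dumps({
                    "genome_id": e.genome.genome_id,
                    "checksum": e.genome.checksum,
                    "source_path": e.genome.source_path,
                    "code": list(e.code.values),
                    "assigned_from": e.assigned_from,
                    "ani_at_assignment": e.ani_at_assignment,
                    "pct_aligned_at_assignment": e.pct_aligned_at_assignment,
                    "assignment_index": e.assignment_index,
                    "trusted": e.trusted,
                }) + "\n")

    @classmethod
    def load(cls, path: str | Path,
             cache: Optional[SimilarityCache] = None) -> "CodeRegistry":
        """Reload a saved registry; genome sequences are re-read from each
        entry's recorded source FASTA path (required to extend the
        registry, since new queries must be aligned against them)."""
        with open(path) as fh:
            lines = [json.loads(l) for l in fh if l.strip()]
        if not lines or lines[0].get("kind") != "anicode-registry":
            raise ValueError(f"{path} is not a registry file")
        header = lines[0]
        reg = cls(
            thresholds=ThresholdTable(positions=tuple(
                (l, float(t)) for l, t in header["thresholds"])),
            ani_config=AniConfig(**header["config"]),
            cache=cache,
        )
        for rec in lines[1:]:
            if not rec.get("source_path"):
                raise ValueError(
                    f"entry {rec['genome_id']!r} has no source_path; "
                    "cannot reload its sequence")
            genome = read_genome(rec["source_path"], rec["genome_id"])
            if genome.checksum != rec["checksum"]:
                raise ValueError(
                    f"sequence at {rec['source_path']} changed since "
                    f"{rec['genome_id']!r} was registered")
            reg._append(RegistryEntry(
                genome=genome,
                code=GenomeCode(values=tuple(rec["code"]),
                                table_ref=reg.thresholds.table_id()),
                assigned_from=rec["assigned_from"],
                ani_at_assignment=rec["ani_at_assignment"],
                pct_aligned_at_assignment=rec["pct_aligned_at_assignment"],
                assignment_index=rec["assignment_index"],
                trusted=rec.get("trusted", True),
            ))
        return reg


def build_registry(genomes: Sequence[GenomeRecord],
                   ani_config: AniConfig = AniConfig(),
                   thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                   cache: Optional[SimilarityCache] = None) -> CodeRegistry:
    """Register genomes strictly in the given order and return the registry."""
    if not genomes:
        raise ValueError("need at least one genome")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in input")
    reg = CodeRegistry(thresholds=thresholds, ani_config=ani_config,
                       cache=cache)
    for g in genomes:
        reg.register(g)
    return reg


def last_shared_position(code1: GenomeCode, code2: GenomeCode
                         ) -> Optional[int]:
    """Largest index k with agreement at all positions 0..k; None when the
    codes already differ at the first position."""
    if code1.table_ref != code2.table_ref:
        raise ValueError("codes use different threshold tables")
    k = -1
    for a, b in zip(code1.values, code2.values):
        if a != b:
            break
        k += 1
    return None if k < 0 else k


def format_code(code: GenomeCode,
                show_positions: Optional[Sequence[str]] = None,
                table: ThresholdTable = DEFAULT_THRESHOLDS) -> str:
    """Canonical text form: "<value>_<label>" tokens joined by "_".

    ``show_positions`` projects the code onto a label subset, e.g.
    V, W, X for near-identical strains.
    """
    labels = _labels_for(code, table)
    if show_positions is not None:
        wanted = list(show_positions)
        for lab in wanted:
            if lab not in labels:
                raise KeyError(f"unknown position label {lab!r}")
        pairs = [(v, l) for v, l in zip(code.values, labels) if l in wanted]
    else:
        pairs = list(zip(code.values, labels))
    return "_".join(f"{v}_{l}" for v, l in pairs)


def parse_code(text: str, table: ThresholdTable = DEFAULT_THRESHOLDS,
               allow_partial: bool = False) -> GenomeCode:
    """Invert :func:`format_code`.

    A full code yields a complete GenomeCode; a projection parses only
    when ``allow_partial`` and yields a partial code (None at unshown
    positions). Labels must appear in table order.
    """
    tokens = [t for t in text.strip().strip("_").split("_") if t != ""]
    if not tokens or len(tokens) % 2 != 0:
        raise CodeParseError("expected value_label token pairs", len(tokens))
    values: List[Optional[int]] = [None] * len(table)
    last_idx = -1
    for off in range(0, len(tokens), 2):
        vtok, ltok = tokens[off], tokens[off + 1]
        try:
            value = int(vtok)
        except ValueError:
            raise CodeParseError(f"malformed value {vtok!r}", off) from None
        if value < 0:
            raise CodeParseError(f"negative value {vtok!r}", off)
        if ltok not in table.labels:
            raise CodeParseError(f"unknown label {ltok!r}", off + 1)
        idx = table.index_of(ltok)
        if idx <= last_idx:
            raise CodeParseError(f"label {ltok!r} out of order", off + 1)
        last_idx = idx
        values[idx] = value
    if any(v is None for v in values):
        if not allow_partial:
            raise CodeParseError(
                "partial code (set allow_partial to accept projections)", 0)
        return GenomeCode(values=tuple(values), table_ref=table.table_id())
    return GenomeCode(values=tuple(values), table_ref=table.table_id())


def _labels_for(code: GenomeCode, table: ThresholdTable) -> Tuple[str, ...]:
    if table.table_id() == code.table_ref:
        return table.labels
    # fall back to reconstructing labels from the code's own table_ref
    try:
        return tuple(tok.split(":")[0] for tok in code.table_ref.split("|"))
    except Exception:  # pragma: no cover - defensive
        raise ValueError("cannot determine position labels for code")
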