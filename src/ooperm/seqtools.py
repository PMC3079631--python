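"""Mutant-construct bookkeeping for aquaporin sequences: point-mutation
grammar ("H53A/G54H/T85A"), NPA/NPT/NPS pore-motif scanning, loop-region
annotation, and verification of the packaged mutant loop-fragment table.

Coordinates are 1-based and inclusive on the full-length reference
numbering; loop fragments carry explicit offsets (local = full - offset).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ProteinSequence",
    "MutationSpec",
    "RegionAnnotation",
    "parse_construct_name",
    "apply_mutations",
    "find_np_motifs",
    "load_loop_table",
    "load_loop_offsets",
    "default_loop_annotations",
    "verify_table",
    "read_fasta",
    "write_fasta",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (20-letter alphabet plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutationSpec:
    """One point substitution, e.g. T85A: wt residue T at position 85
    replaced by A.  Position is 1-based on the reference numbering."""

    wt_residue: str
    position: int
    new_residue: str

    def __post_init__(self) -> None:
        if len(self.wt_residue) != 1 or self.wt_residue not in AA_ALPHABET:
            raise ValueError(f"invalid wt residue {self.wt_residue!r}")
        if len(self.new_residue) != 1 or self.new_residue not in AA_ALPHABET:
            raise ValueError(f"invalid new residue {self.new_residue!r}")
        if self.wt_residue == self.new_residue:
            raise ValueError("wt and new residue must differ")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"

    def inverse(self) -> "MutationSpec":
        return MutationSpec(self.new_residue, self.position, self.wt_residue)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named region (loop or transmembrane domain) on the reference
    sequence, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("require 1 <= start <= end")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def parse_construct_name(name: str) -> list[MutationSpec]:
    """Parse a construct name like "H53A/G54H/T85A" into an ordered list
    of :class:`MutationSpec`; "WT" parses to an empty list."""
    name = name.strip()
    if name in ("WT", "wt"):
        return []
    specs = []
    for token in name.split("/"):
        m = _MUTATION_RE.match(token)
        if m is None:
            raise ValueError(f"malformed mutation token {token!r} in {name!r}")
        specs.append(MutationSpec(m.group(1), int(m.group(2)), m.group(3)))
    return specs


def apply_mutations(
    seq: ProteinSequence,
    specs: Sequence[MutationSpec],
    offset: int = 0,
) -> ProteinSequence:
    """Apply point mutations to ``seq``, whose first residue sits at
    reference position ``offset + 1``.

    Raises if a stated wild-type residue does not match the sequence at
    its position, reporting expected vs found.
    """
    residues = list(seq.residues)
    for spec in specs:
        local = spec.position - offset
        if not 1 <= local <= len(residues):
            raise ValueError(
                f"{spec.name}: position {spec.position} (local {local}) "
                f"outside sequence of length {len(residues)}"
            )
        found = residues[local - 1]
        if found != spec.wt_residue:
            raise ValueError(
                f"{spec.name}: expected {spec.wt_residue} at position "
                f"{spec.position}, found {found}"
            )
        residues[local - 1] = spec.new_residue
    suffix = "/".join(s.name for s in specs)
    new_id = f"{seq.id}|{suffix}" if suffix else seq.id
    return ProteinSequence(id=new_id, residues="".join(residues))


def find_np_motifs(
    seq: ProteinSequence,
    third_residues: Iterable[str] = ("A", "T", "S"),
) -> list[tuple[int, str]]:
    """All N-P-X triplets (X in ``third_residues``) with their 1-based
    start positions, in order.  NPA is the canonical aquaporin pore box;
    NPT/NPS are naturally occurring variants."""
    third = "".join(sorted(set(third_residues)))
    pattern = re.compile(rf"(?=NP[{re.escape(third)}])")
    return [
        (m.start() + 1, seq.residues[m.start() : m.start() + 3])
        for m in pattern.finditer(seq.residues)
    ]


def is_canonical_np_motif(triplet: str) -> bool:
    return triplet == "NPA"


# ---------------------------------------------------------------------------
# packaged mutant loop-fragment table

LOOP_NAMES = ("loop_A", "loop_B", "loop_C", "loop_D", "loop_E")


def _data_text(filename: str) -> str:
    return resources.files("ooperm.data").joinpath(filename).read_text()


def load_loop_table() -> dict[str, dict[str, str]]:
    """The packaged construct table: construct name -> loop name ->
    fragment sequence."""
    reader = csv.DictReader(_data_text("table2_loops.tsv").splitlines(), delimiter="\t")
    table = {}
    for row in reader:
        table[row["construct"]] = {name: row[name] for name in LOOP_NAMES}
    return table


def load_loop_offsets() -> dict[str, int]:
    """Loop-fragment offsets on the full-length reference numbering."""
    raw = json.loads(_data_text("loop_offsets.json"))
    return {k: int(v) for k, v in raw.items() if k in LOOP_NAMES}


def default_loop_annotations() -> list[RegionAnnotation]:
    """Loop regions implied by the packaged fragments and offsets."""
    table = load_loop_table()
    offsets = load_loop_offsets()
    wt = table["WT"]
    return [
        RegionAnnotation(
            name=name.replace("_", " "),
            start=offsets[name] + 1,
            end=offsets[name] + len(wt[name]),
        )
        for name in LOOP_NAMES
    ]


def verify_table(
    table: Optional[Mapping[str, Mapping[str, str]]] = None,
    offsets: Optional[Mapping[str, int]] = None,
) -> dict:
    """Check that applying each construct's parsed mutations to the WT
    loop fragments reproduces the packaged mutant fragments exactly.

    Returns a report dict: ``results`` maps construct name to "pass" or
    a mismatch description; ``n_pass``/``n_fail`` summarise.
    """
    if table is None:
        table = load_loop_table()
    if offsets is None:
        offsets = load_loop_offsets()
    if "WT" not in table:
        raise ValueError("fixture table lacks a WT row")
    wt = table["WT"]
    results: dict[str, str] = {}
    for construct, loops in table.items():
        if construct == "WT":
            continue
        try:
            specs = parse_construct_name(construct)
        except ValueError as exc:
            results[construct] = f"unparseable name: {exc}"
            continue
        problems = []
        claimed = {s.position for s in specs}
        for name in LOOP_NAMES:
            offset = offsets[name]
            length = len(wt[name])
            local_specs = [
                s for s in specs if offset + 1 <= s.position <= offset + length
            ]
            claimed -= {s.position for s in local_specs}
            try:
                mutated = apply_mutations(
                    ProteinSequence(id=name, residues=wt[name]),
                    local_specs,
                    offset=offset,
                )
            except ValueError as exc:
                problems.append(str(exc))
                continue
            if mutated.residues != loops[name]:
                diff = [
                    f"pos {offset + i + 1}: built {a} vs fixture {b}"
                    for i, (a, b) in enumerate(zip(mutated.residues, loops[name]))
                    if a != b
                ]
                problems.append(f"{name}: " + "; ".join(diff))
        if claimed:
            problems.append(f"mutations outside all loops: {sorted(claimed)}")
        results[construct] = "pass" if not problems else " | ".join(problems)
    n_pass = sum(1 for v in results.values() if v == "pass")
    return {
        "results": results,
        "n_pass": n_pass,
        "n_fail": len(results) - n_pass,
    }


# ---------------------------------------------------------------------------
# FASTA I/O (plain text, single or multi record)

def read_fasta(path) -> list[ProteinSequence]:
    records = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(ProteinSequence(name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append(ProteinSequence(name, "".join(chunks)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
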