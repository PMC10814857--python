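"""Proline-rich motif (PRM) consensus classes: grammar, compilation, scanning.

SH3 domains recognize short proline-rich stretches described in the field by a
consensus grammar: a fixed residue letter means exactly that amino acid, ``X``
means any standard residue, and an alternation — written ``[KR]`` or ``(K/R)``
interchangeably — means any residue of the listed set.  The packaged default
registry holds the 14 consensus classes used for proline-rich-domain
annotation; a larger family registry additionally carries the per-family
specificity motifs (see :mod:`sh3prm.specificity`).

Matches are boolean (a window matches or it does not); overlapping and nested
matches are all reported, because motif *co-occurrence* within a sequence is
the quantity of interest, not a non-overlapping placement count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

MIN_PATTERN_LENGTH = 3


class MotifParseError(ValueError):
    """Raised for a malformed motif specification string."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled PRM consensus class.

    Parameters
    ----------
    class_id : str
        Normalized identifier, e.g. ``"PXXPX[KR]"``.
    elements : tuple of frozenset of str
        One allowed-residue set per position.  ``X`` compiles to the full
        standard alphabet.
    family_links : frozenset of int
        SH3 specificity families whose motif lists include this class
        (empty when the pattern is not family-linked).
    """

    class_id: str
    elements: tuple[frozenset[str], ...]
    family_links: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.elements) < MIN_PATTERN_LENGTH:
            raise MotifParseError(
                f"pattern {self.class_id!r} has length {len(self.elements)}; "
                f"minimum is {MIN_PATTERN_LENGTH}"
            )
        for i, el in enumerate(self.elements, start=1):
            if not el or not el <= _STANDARD_SET:
                raise MotifParseError(
                    f"pattern {self.class_id!r} position {i} constrains no "
                    "standard residue"
                )
        if not any(el == frozenset("P") for el in self.elements):
            raise MotifParseError(
                f"pattern {self.class_id!r} has no fixed proline position"
            )

    @property
    def length(self) -> int:
        return len(self.elements)

    def matches_window(self, window: str) -> bool:
        """Exact per-position check of a window of ``self.length`` residues."""
        if len(window) != self.length:
            return False
        return all(c in el for c, el in zip(window.upper(), self.elements))

    @property
    def regex(self) -> re.Pattern[str]:
        parts = []
        for el in self.elements:
            if el == _STANDARD_SET:
                parts.append(f"[{STANDARD_AA}]")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        # lookahead so overlapping occurrences are all found
        return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif class in a subject sequence (1-based, inclusive)."""

    class_id: str
    sequence_id: str
    start: int
    end: int
    matched_text: str


_ALTERNATION = re.compile(r"\[([A-Za-z]+)\]|\(([A-Za-z/]+)\)")


def _normalize_spec(spec: str) -> str:
    """Normalize alternation spellings: ``(K/R)`` and ``[KR]`` -> ``[KR]``."""

    def repl(m: re.Match[str]) -> str:
        raw = m.group(1) or m.group(2)
        if m.group(2) is not None:  # slash form: every alternative nonempty
            parts = raw.split("/")
            if not all(parts):
                raise MotifParseError(f"malformed alternation ({raw}) in {spec!r}")
        body = raw.replace("/", "").upper()
        return f"[{body}]"

    return _ALTERNATION.sub(repl, spec.strip().upper())


def compile_pattern(
    spec: str,
    class_id: str | None = None,
    family_links: Iterable[int] = (),
) -> MotifPattern:
    """Compile a motif specification string into a :class:`MotifPattern`.

    ``spec`` uses the consensus grammar: residue letters are fixed positions,
    ``X`` matches any of the 20 standard residues, and ``[KR]`` / ``(K/R)`` /
    ``(L/A)`` are alternations over the listed residues.

    >>> p = compile_pattern("PXXPX(K/R)")
    >>> p.length, p.class_id
    (6, 'PXXPX[KR]')
    """
    if not spec or not spec.strip():
        raise MotifParseError("empty motif specification")
    norm = _normalize_spec(spec)
    elements: list[frozenset[str]] = []
    i = 0
    while i < len(norm):
        c = norm[i]
        if c == "[":
            j = norm.find("]", i)
            if j < 0:
                raise MotifParseError(
                    f"unterminated alternation starting at {norm[i:]!r} in {spec!r}"
                )
            body = norm[i + 1 : j]
            if not body or not set(body) <= _STANDARD_SET:
                raise MotifParseError(
                    f"malformed alternation {norm[i:j + 1]!r} in {spec!r}"
                )
            elements.append(frozenset(body))
            i = j + 1
        elif c == "X":
            elements.append(_STANDARD_SET)
            i += 1
        elif c in _STANDARD_SET:
            elements.append(frozenset(c))
            i += 1
        else:
            raise MotifParseError(f"unexpected token {c!r} in motif spec {spec!r}")
    return MotifPattern(
        class_id=class_id or norm,
        elements=tuple(elements),
        family_links=frozenset(family_links),
    )


class MotifRegistry:
    """A keyed collection of compiled motif classes."""

    def __init__(self, patterns: Iterable[MotifPattern], version: str = "unversioned"):
        self.version = version
        self._patterns: dict[str, MotifPattern] = {}
        for p in patterns:
            if p.class_id in self._patterns:
                raise ValueError(f"duplicate class_id {p.class_id!r}")
            self._patterns[p.class_id] = p

    def __len__(self) -> int:
        return len(self._patterns)

    def __iter__(self):
        return iter(self._patterns.values())

    def __contains__(self, class_id: str) -> bool:
        return class_id in self._patterns

    def __getitem__(self, class_id: str) -> MotifPattern:
        return self._patterns[class_id]

    @property
    def class_ids(self) -> list[str]:
        return list(self._patterns)

    @classmethod
    def from_tsv(cls, path) -> "MotifRegistry":
        """Load a registry from a TSV with columns class_id, spec, family_links."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        patterns = []
        for _, row in df.iterrows():
            links = [int(t) for t in str(row.get("family_links", "")).split(",") if t.strip()]
            patterns.append(
                compile_pattern(row["spec"], class_id=row["class_id"], family_links=links)
            )
        return cls(patterns, version=str(path))

    def to_tsv(self, path) -> None:
        rows = []
        for p in self:
            rows.append(
                {
                    "class_id": p.class_id,
                    "spec": p.class_id,
                    "family_links": ",".join(str(f) for f in sorted(p.family_links)),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_registry() -> MotifRegistry:
    """The packaged 14-class PRM consensus registry."""
    with resources.as_file(
        resources.files("sh3prm.data") / "prm_registry.tsv"
    ) as p:
        reg = MotifRegistry.from_tsv(p)
    reg.version = "prm-consensus-14"
    return reg


def _clean_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence is not scannable")
    return seq


def scan_sequence(
    seq: str, registry: MotifRegistry, sequence_id: str = "seq"
) -> list[MotifMatch]:
    """Report every occurrence of every registry class in ``seq``.

    All windows of each pattern's length are tested; overlapping and nested
    occurrences are all reported.  Output is sorted by (start, class_id).
    Non-standard residue letters (e.g. ``B``, ``Z``) match nothing, including
    ``X`` positions.
    """
    if len(registry) == 0:
        raise ValueError("empty motif registry")
    seq = _clean_sequence(seq)
    out: list[MotifMatch] = []
    for pat in registry:
        for m in pat.regex.finditer(seq):
            start = m.start() + 1
            out.append(
                MotifMatch(
                    class_id=pat.class_id,
                    sequence_id=sequence_id,
                    start=start,
                    end=start + pat.length - 1,
                    matched_text=m.group(1),
                )
            )
    out.sort(key=lambda m: (m.start, m.class_id))
    return out


def annotate_prd(
    seq: str, registry: MotifRegistry, sequence_id: str = "seq"
) -> pd.DataFrame:
    """Per-class presence/count table for a proline-rich domain.

    Returns one row per registry class with columns ``class_id``, ``present``,
    ``match_count``; the counts sum to the total number of scan matches.
    """
    matches = scan_sequence(seq, registry, sequence_id=sequence_id)
    counts = {cid: 0 for cid in registry.class_ids}
    for m in matches:
        counts[m.class_id] += 1
    return pd.DataFrame(
        {
            "class_id": list(counts),
            "present": [c >= 1 for c in counts.values()],
            "match_count": list(counts.values()),
        }
    )


def matches_to_frame(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Matches as a TSV-ready table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "sequence_id": m.sequence_id,
                "class_id": m.class_id,
                "start": m.start,
                "end": m.end,
                "matched_text": m.matched_text,
            }
            for m in matches
        ],
        columns=["sequence_id", "class_id", "start", "end", "matched_text"],
    )


def matches_to_bed(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """BED-dialect table: 0-based half-open start/end."""
    return pd.DataFrame(
        [
            {
                "sequence_id": m.sequence_id,
                "start": m.start - 1,
                "end": m.end,
                "class_id": m.class_id,
            }
            for m in matches
        ],
        columns=["sequence_id", "start", "end", "class_id"],
    )
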