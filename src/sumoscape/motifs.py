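"""SUMOylation consensus-motif scanning.

Patterns are written in a small character-class language over the 20
standard amino acids: each position is a literal residue or a bracketed
residue set (``[IV]KE``), and a single bounded-window construct of the
form ``<n>[SET]R`` is allowed.  The window form has two readings:

* default: residue ``R`` preceded by at least one residue of ``SET``
  within the ``n`` immediately N-terminal positions (so ``5[ED]K`` is a
  lysine with an acidic residue among the five positions before it);
* literal (``literal_window=True``): ``SET`` repeated exactly ``n`` times
  followed by ``R``.

Ambiguity codes ``X``/``B``/``Z`` and selenocysteine ``U`` never match
any pattern position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .proteome import STANDARD_RESIDUES, ProteinRecord


class MotifError(ValueError):
    """Raised for malformed motif patterns."""


# internal token: frozenset of residues allowed at one position
Token = frozenset


def _parse_tokens(body: str, pattern: str) -> list[Token]:
    tokens: list[Token] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == "[":
            j = body.find("]", i)
            if j < 0:
                raise MotifError(f"{pattern!r}: unclosed bracket")
            residues = body[i + 1 : j]
            if not residues or not set(residues) <= STANDARD_RESIDUES:
                raise MotifError(f"{pattern!r}: bad residue class [{residues}]")
            tokens.append(frozenset(residues))
            i = j + 1
        elif c in STANDARD_RESIDUES:
            tokens.append(frozenset(c))
            i += 1
        else:
            raise MotifError(f"{pattern!r}: unexpected character {c!r}")
    if not tokens:
        raise MotifError(f"{pattern!r}: empty pattern")
    return tokens


@dataclass(frozen=True)
class MotifPattern:
    """One named consensus pattern, compiled at construction."""

    name: str
    pattern: str
    literal_window: bool = False
    # compiled form, filled in __post_init__
    _tokens: tuple = field(default=(), repr=False, compare=False)
    _window: int = field(default=0, repr=False, compare=False)

    def __post_init__(self) -> None:
        pat = self.pattern
        digits = ""
        while pat and pat[0].isdigit():
            digits += pat[0]
            pat = pat[1:]
        if digits:
            window = int(digits)
            if window < 1:
                raise MotifError(f"{self.pattern!r}: window must be >= 1")
            tokens = _parse_tokens(pat, self.pattern)
            if len(tokens) != 2:
                raise MotifError(
                    f"{self.pattern!r}: window construct must be <n>[SET]<residue>"
                )
            if self.literal_window:
                tokens = [tokens[0]] * window + [tokens[1]]
                window = 0
        else:
            tokens = _parse_tokens(pat, self.pattern)
            window = 0
        object.__setattr__(self, "_tokens", tuple(tokens))
        object.__setattr__(self, "_window", window)

    def match_at(self, seq: str, start: int) -> bool:
        """Does the pattern match at 0-based position ``start``?"""
        if self._window == 0:
            tokens = self._tokens
            if start + len(tokens) > len(seq):
                return False
            return all(seq[start + k] in tok for k, tok in enumerate(tokens))
        # windowed: SET residue at start, anchor residue within the next
        # `window` positions, intervening residues standard
        cls, anchor = self._tokens
        if start >= len(seq) or seq[start] not in cls:
            return False
        for gap in range(self._window):
            pos = start + 1 + gap
            if pos >= len(seq):
                return False
            if seq[pos] in anchor:
                return True
            if seq[pos] not in STANDARD_RESIDUES:
                return False
        return False


#: The four consensus pattern heads used for human SUMO-target analysis.
DEFAULT_PATTERNS = ("[IV]KE", "[VF]K[QTEP][ED]", "[PKE]KE[ED]", "5[ED]K")


@dataclass
class MotifSet:
    """Ordered collection of uniquely named motif patterns."""

    motifs: list[MotifPattern]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise MotifError("duplicate motif names")

    @classmethod
    def default(cls, literal_window: bool = False) -> "MotifSet":
        return cls(
            [MotifPattern(p, p, literal_window=literal_window) for p in DEFAULT_PATTERNS]
        )

    @classmethod
    def from_file(cls, path: str | Path, literal_window: bool = False) -> "MotifSet":
        """Read ``name TAB pattern`` lines (``#`` comments allowed)."""
        motifs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, pattern = line.partition("\t")
            if not pattern:
                name = pattern = line
            motifs.append(MotifPattern(name, pattern, literal_window=literal_window))
        if not motifs:
            raise MotifError(f"{path}: no motif definitions")
        return cls(motifs)

    def names(self) -> list[str]:
        return [m.name for m in self.motifs]

    def __iter__(self):
        return iter(self.motifs)


@dataclass
class MotifSummary:
    """Sequence-level motif content of a protein set."""

    set_size: int
    per_motif: dict[str, int]
    any_motif: int

    @property
    def any_motif_pct(self) -> float:
        return 100.0 * self.any_motif / self.set_size


def scan_protein(seq: str, motifs: MotifSet) -> dict[str, list[int]]:
    """All (possibly overlapping) 1-based match start positions per motif."""
    seq = seq.upper()
    out: dict[str, list[int]] = {}
    for motif in motifs:
        out[motif.name] = [
            i + 1 for i in range(len(seq)) if motif.match_at(seq, i)
        ]
    return out


def summarize_set(
    proteins: Sequence[ProteinRecord] | Iterable[ProteinRecord],
    motifs: MotifSet | None = None,
) -> MotifSummary:
    """Count sequences containing at least one match per motif and overall.

    A protein counts once per motif regardless of match multiplicity;
    summaries are additive over partitions of the set.
    """
    if motifs is None:
        motifs = MotifSet.default()
    proteins = list(proteins)
    if not proteins:
        raise MotifError("empty protein collection")
    per_motif = dict.fromkeys(motifs.names(), 0)
    any_motif = 0
    for rec in proteins:
        hits = scan_protein(rec.sequence, motifs)
        found_any = False
        for name, positions in hits.items():
            if positions:
                per_motif[name] += 1
                found_any = True
        if found_any:
            any_motif += 1
    return MotifSummary(set_size=len(proteins), per_motif=per_motif, any_motif=any_motif)
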