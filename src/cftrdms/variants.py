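"""Variant identifier parsing and CFTR domain assignment.

Variant ids are HGVS-like protein notation without the ``p.`` prefix:
missense as ``V232D``, deletions as ``F508del`` (the alias ``ΔF508`` is
accepted and canonicalised). The residue number embedded in the id drives
domain assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_MISSENSE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DELETION = re.compile(r"^([A-Z])(\d+)del$")
_DELTA = re.compile(r"^(?:Δ|del)([A-Z])(\d+)$")  # ΔF508 / delF508

#: Standard CFTR topology boundaries (1-based inclusive residue intervals).
#: Only the NBD2 interval is fixed by convention at 1201-1436; the others are
#: configurable defaults covering the canonical 1480-residue protein.
DEFAULT_CFTR_DOMAINS: dict[str, tuple[int, int]] = {
    "MSD1": (1, 394),
    "NBD1": (395, 646),
    "R": (647, 845),
    "MSD2": (846, 1200),
    "NBD2": (1201, 1436),
}

CFTR_LENGTH = 1480


def normalize_variant_id(variant_id: str) -> str:
    """Canonicalise a variant id (``ΔF508`` -> ``F508del``)."""
    vid = variant_id.strip()
    m = _DELTA.match(vid)
    if m:
        return f"{m.group(1)}{m.group(2)}del"
    return vid


def parse_residue(variant_id: str) -> int:
    """Extract the 1-based residue position from a variant id.

    Raises ``ValueError`` for ids that carry no parseable position.
    """
    vid = normalize_variant_id(variant_id)
    for pat in (_MISSENSE, _DELETION):
        m = pat.match(vid)
        if m:
            return int(m.group(2))
    raise ValueError(f"cannot parse residue position from variant id {variant_id!r}")


@dataclass
class DomainMap:
    """Named, non-overlapping residue intervals over the CFTR sequence."""

    intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CFTR_DOMAINS)
    )
    protein_length: int = CFTR_LENGTH

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (s, e) in spans:
            if not (1 <= s <= e <= self.protein_length):
                raise ValueError(f"interval ({s}, {e}) outside 1..{self.protein_length}")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("domain intervals overlap")

    def assign(self, variant_id: str) -> str | None:
        """Domain name for a variant, or None if unassigned/unparseable."""
        try:
            pos = parse_residue(variant_id)
        except ValueError:
            return None
        for name, (s, e) in self.intervals.items():
            if s <= pos <= e:
                return name
        return None
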