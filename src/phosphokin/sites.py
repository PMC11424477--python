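"""Phosphosite keys and site-group keys.

A *phosphosite key* names one phosphorylated residue on a protein in the
canonical form ``"PROTEIN_ResPos"`` (e.g. ``"P1_S45"``): protein identifier,
underscore, residue letter (S, T or Y), one-based position.

A *site-group key* names the full set of phosphosites carried by a peptide.
Peptides carrying the same set are quantified together as one unit, so the
key is the protein followed by the sorted residue+position tokens joined by
semicolons, e.g. ``"P1_S45;S49"``.
"""

from __future__ import annotations

import re

from .errors import ParseError

PHOSPHO_RESIDUES = frozenset("STY")

_SITE_RE = re.compile(r"^(?P<res>[STY])(?P<pos>[1-9]\d*)$")


def parse_site_key(key: str) -> tuple[str, str, int]:
    """Split a phosphosite key into (protein, residue, position).

    The protein identifier may itself contain underscores; the residue token
    is whatever follows the *last* underscore.
    """
    protein, _, token = key.rpartition("_")
    if not protein:
        raise ParseError(f"malformed phosphosite key {key!r}: missing protein part")
    m = _SITE_RE.match(token)
    if m is None:
        raise ParseError(
            f"malformed phosphosite key {key!r}: expected residue in S/T/Y "
            f"followed by a positive integer position, got {token!r}"
        )
    return protein, m.group("res"), int(m.group("pos"))


def make_site_key(protein: str, residue: str, position: int) -> str:
    if residue not in PHOSPHO_RESIDUES:
        raise ParseError(f"residue {residue!r} is not a phosphorylatable residue (S/T/Y)")
    if not isinstance(position, (int,)) or position < 1:
        raise ParseError(f"position {position!r} must be a positive integer")
    return f"{protein}_{residue}{position}"


def make_group_key(site_keys) -> str:
    """Canonical site-group key for a non-empty set of phosphosite keys.

    All keys must live on the same protein. Sites are sorted by position,
    then residue, and joined with semicolons after a single protein prefix.
    """
    keys = list(site_keys)
    if not keys:
        raise ParseError("site group must contain at least one phosphosite")
    parsed = [parse_site_key(k) for k in keys]
    proteins = {p for p, _, _ in parsed}
    if len(proteins) > 1:
        raise ParseError(f"site group spans multiple proteins: {sorted(proteins)}")
    protein = parsed[0][0]
    tokens = sorted({(pos, res) for _, res, pos in parsed})
    return protein + "_" + ";".join(f"{res}{pos}" for pos, res in tokens)


def group_key_sites(group_key: str) -> list[str]:
    """Expand a canonical site-group key back into full phosphosite keys."""
    head, *rest = group_key.split(";")
    protein, _, first = head.rpartition("_")
    if not protein or _SITE_RE.match(first) is None:
        raise ParseError(f"malformed site-group key {group_key!r}")
    out = [f"{protein}_{first}"]
    for token in rest:
        m = _SITE_RE.match(token)
        if m is None:
            raise ParseError(f"malformed site token {token!r} in group key {group_key!r}")
        out.append(f"{protein}_{token}")
    return out
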