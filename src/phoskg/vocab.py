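"""Relation vocabulary and amino-acid alphabet shared across the package."""

from __future__ import annotations

#: The 32 shipped relation names. ``residue_1`` … ``residue_9`` carry the
#: positional composition of 9-mer motifs; the rest link proteins to their
#: functional, structural and expression context.
RESIDUE_RELATIONS: tuple[str, ...] = tuple(f"residue_{i}" for i in range(1, 10))

DEFAULT_RELATIONS: frozenset[str] = frozenset(
    (
        "participating_pathway",
        "part_of_complex",
        "pathway_event_of",
        "bio_process",
        "regulates",
        "positively_regulates",
        "negatively_regulates",
        "mol_func",
        "capable_of",
        "capable_of_part_of",
        "cellular_comp",
        "occurs_in",
        "part_of",
        "expressed_in",
        "is_a",
        "has_domain",
        "belongs_to_family",
        "homologous_superfamily",
        "is_a(domain)",
        "is_a(family)",
        "is_a(form)",
        "k_specific_motif",
        "has_motif",
    )
    + RESIDUE_RELATIONS
)

#: Standard 20 amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol used when a 9-mer window overlaps a protein terminus.
PAD: str = "_"

#: Non-standard residues are collapsed onto X so the alphabet stays closed.
NONSTANDARD_TO_X: frozenset[str] = frozenset("UBZXO")

PHOSPHOACCEPTORS: frozenset[str] = frozenset("STY")

MOTIF_LENGTH: int = 9
CENTER_INDEX: int = 4  # 0-based position of the phosphoacceptor


def residue_node(char: str) -> str:
    """Map a motif character to its amino-acid node identifier.

    Standard residues map to ``aa_<char>``, the padding symbol to ``aa__``,
    and non-standard residues (U, B, Z, X, O) to ``aa_X``. Anything else is
    rejected rather than silently dropped.
    """
    c = char.upper()
    if c in AMINO_ACIDS:
        return f"aa_{c}"
    if char == PAD:
        return "aa__"
    if c in NONSTANDARD_TO_X:
        return "aa_X"
    raise ValueError(f"character {char!r} is not a residue, pad, or known non-standard code")
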