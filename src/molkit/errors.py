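"""Error types raised while building or manipulating structures."""

from __future__ import annotations


class StructureError(ValueError):
    """A structure is chemically invalid or a SMILES cannot be interpreted.

    Categories mirror the distinct failure modes of parsing and validation:
    bonding-law violations, conflicting double-bond stereochemistry, syntax
    errors and chirality errors. When raised during parsing, the message is
    prefixed with the offending SMILES.
    """

    BONDING = "Basic bonding laws have been violated"
    STEREO_CONFLICT = "Conflicting double bond stereochemistry"
    SYNTAX = "Invalid SMILES syntax"
    CHIRALITY = "Invalid chirality specification"

    def __init__(self, category: str, detail: str = "", smiles: str | None = None):
        self.category = category
        self.detail = detail
        self.smiles = smiles
        text = category if not detail else f"{category} ({detail})"
        if smiles is not None:
            text = f'Error parsing "{smiles}": {text}'
        super().__init__(text)

    def with_smiles(self, smiles: str) -> "StructureError":
        return StructureError(self.category, self.detail, smiles)


class ChiralityError(StructureError):
    """Raised when declared stereochemistry cannot be honoured in 2D."""

    def __init__(self, detail: str = "", smiles: str | None = None):
        super().__init__(StructureError.CHIRALITY, detail, smiles)
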