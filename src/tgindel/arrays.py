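"""Tandem transgene array model and rendering.

Pronuclear-injection transgenes integrate as head-to-tail multimer arrays.
The arrays characterized here additionally contain a single internal
orientation switch: copies before ``switch_index`` run 3'->5' (i.e. are
reverse-complemented in the rendered sequence) and copies from
``switch_index`` on run 5'->3'. An optional spacer (e.g. a cloning-vector
fragment) sits at the inversion point, and the terminal copies may be
partial.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_dna, revcomp
from .monomer import TransgeneMonomer


@dataclass(frozen=True)
class ArrayModel:
    """Truth/inference description of one transgene array."""

    n_copies: int
    switch_index: int = 0
    spacer: str = ""
    five_prime_partial: int = 0
    three_prime_partial: int = 0

    @property
    def has_switch(self) -> bool:
        return 0 < self.switch_index < self.n_copies

    def rendered_length(self, monomer_length: int) -> int:
        return (
            self.n_copies * monomer_length
            - self.five_prime_partial
            - self.three_prime_partial
            + len(self.spacer)
        )

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if not 0 <= self.switch_index <= self.n_copies:
            raise ValueError("switch_index must lie in [0, n_copies]")
        if self.five_prime_partial < 0 or self.three_prime_partial < 0:
            raise ValueError("terminal truncations must be >= 0")
        if self.spacer:
            check_dna(self.spacer, "spacer")


def render_array(monomer: TransgeneMonomer, model: ArrayModel) -> str:
    """Render the array sequence carried on the transgenic haplotype.

    Copies with index < ``switch_index`` are reverse-complemented
    (3'->5' block first, mirroring the characterized alleles), the spacer
    is inserted at the switch point, and the 5'/3' terminal truncations
    are applied to the first/last rendered copy.
    """
    mono = monomer.sequence
    L = len(mono)
    if model.five_prime_partial >= L or model.three_prime_partial >= L:
        raise ValueError("terminal truncation must be shorter than the monomer")

    rc = revcomp(mono)
    blocks = [rc] * model.switch_index
    blocks.append(model.spacer)  # sits at the inversion point
    blocks.extend([mono] * (model.n_copies - model.switch_index))
    out = "".join(blocks)
    if model.five_prime_partial:
        out = out[model.five_prime_partial:]
    if model.three_prime_partial:
        out = out[: len(out) - model.three_prime_partial]
    return out
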