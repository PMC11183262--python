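"""Gene signatures: plain-text lists of gene symbols, one per line.

Signature files use ``#`` for comments and blank lines are ignored. The
package ships a small set of curated mouse mammary signatures under
``mammodev/data`` — a 13-gene proliferation program and example
basal/luminal/LP/ML marker lists assembled from well-established lineage
markers — all editable and replaceable by user-supplied files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["GeneSignature", "read_signature", "load_packaged_signature"]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set used for per-cell identity scoring."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def _parse(text: str, name: str) -> GeneSignature:
    genes = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GeneSignature(name=name, genes=tuple(genes))


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a one-symbol-per-line signature file."""
    path = Path(path)
    return _parse(path.read_text(), name or path.stem)


def load_packaged_signature(name: str) -> GeneSignature:
    """Load one of the signatures shipped with the package.

    Available names: ``proliferation``, ``basal``, ``luminal``,
    ``luminal_progenitor``, ``mature_luminal``.
    """
    ref = resources.files("mammodev.data").joinpath(f"{name}.txt")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"no packaged signature named {name!r}") from None
    return _parse(text, name)
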