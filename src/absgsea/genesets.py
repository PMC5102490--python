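"""Gene-set collections and GMT file I/O.

GMT dialect: one set per line, tab-separated — name, description, then the
member gene identifiers.  The reader tolerates CRLF line endings and
trailing tabs, deduplicates genes within a set (first occurrence wins) and
rejects duplicate set names.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterator, Mapping

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]


class GeneSetCollection(Mapping):
    """Ordered mapping of set name -> list of gene identifiers."""

    def __init__(self, sets: Mapping[str, list[str]], descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g, None)
            self._sets[name] = list(seen)
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self._sets.items()}

    def restrict(self, genes, min_size: int = 10, max_size: int = 300) -> "GeneSetCollection":
        """Intersect every set with ``genes`` and keep sets whose resulting
        size lies in ``[min_size, max_size]`` (both inclusive).

        The effective size of a set is the number of its genes present in
        the data, which is the size the bounds apply to.
        """
        present = set(genes)
        kept = {}
        for name, members in self._sets.items():
            inter = [g for g in members if g in present]
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
        if not kept:
            warnings.warn(
                "no gene-set passed the size filter "
                f"[{min_size}, {max_size}]",
                stacklevel=2,
            )
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene (tab-separated)"
                )
            name, description, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                warnings.warn(
                    f"{path}:{lineno}: dropping empty gene-set {name!r}",
                    stacklevel=2,
                )
                continue
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection, path) -> None:
    """Write sets (a mapping name -> genes) as GMT."""
    descriptions = getattr(collection, "descriptions", {})
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc or "na", *collection[name]]) + "\n")
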