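"""Mutation channel schemas.

A channel schema fixes the identity and order of the rows of every count,
signature, and exposure-compatible matrix. The two standard schemas are the
96-channel single-base-substitution schema (pyrimidine-referenced substitution
classes in trinucleotide context) and the 83-channel small insertion/deletion
schema, both in COSMIC v3 ordering. Arbitrary custom schemas are supported for
toy problems and non-standard channel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class SchemaError(ValueError):
    """Raised when channel labels do not form a recognized or valid schema."""


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered, named set of mutation channel labels."""

    name: str
    labels: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError(f"schema {self.name!r} has duplicate channel labels")
        if len(self.labels) == 0:
            raise SchemaError(f"schema {self.name!r} has no channels")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> list[int]:
        """Positions of ``labels`` in this schema's canonical order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return [pos[lab] for lab in labels]
        except KeyError as exc:
            raise SchemaError(f"label {exc.args[0]!r} not in schema {self.name}") from exc


def _sbs96_labels() -> tuple[str, ...]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return tuple(
        f"{five}[{sub}]{three}" for sub in subs for five in bases for three in bases
    )


def _id83_labels() -> tuple[str, ...]:
    labels: list[str] = []
    # 1-bp deletions and insertions, by base and homopolymer length
    for kind in ("Del", "Ins"):
        for base in ("C", "T"):
            for size in range(6):
                labels.append(f"1:{kind}:{base}:{size}")
    # >=2-bp deletions and insertions at repeats
    for kind in ("Del", "Ins"):
        for length in range(2, 6):
            for size in range(6):
                labels.append(f"{length}:{kind}:R:{size}")
    # microhomology deletions: length-L deletion admits 1..L-1 bp of homology
    # (the length-5 class is "5+", hence up to 5)
    for length in range(2, 6):
        for mh in range(1, (length - 1 if length < 5 else 5) + 1):
            labels.append(f"{length}:Del:M:{mh}")
    return tuple(labels)


SBS96 = ChannelSchema("SBS96", _sbs96_labels())
ID83 = ChannelSchema("ID83", _id83_labels())

_REGISTRY = {"SBS96": SBS96, "ID83": ID83}


def get_schema(name: str) -> ChannelSchema:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SchemaError(
            f"unknown schema {name!r}; known schemas: {sorted(_REGISTRY)}"
        ) from None


def infer_schema(labels) -> ChannelSchema:
    """Match a label set against the registered schemas (order-insensitive)."""
    labset = set(labels)
    for schema in _REGISTRY.values():
        if labset == set(schema.labels):
            return schema
    raise SchemaError(
        f"channel label set (p={len(labset)}) does not match any known schema"
    )
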