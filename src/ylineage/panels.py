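"""Y-STR panel definitions.

A *marker* is a physical amplicon (e.g. DYS385, which amplifies two loci at
once); an *allelic series* is one column of the analysis table after
multi-copy markers are expanded into sorted "a"/"b" series and DYS389II is
re-expressed as DYS389b (DYS389II minus DYS389I).  All downstream statistics
operate on series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "Locus",
    "PanelDefinition",
    "yfiler17",
    "yfiler_plus27",
    "read_panel",
    "RM_SERIES",
]

#: The seven rapidly mutating allelic series (six markers; DYF387S1 counts
#: twice after expansion).  Per-generation mutation rates for these are on
#: the order of 1e-2, an order of magnitude above typical Y-STRs.
RM_SERIES = frozenset(
    {"DYF387S1a", "DYF387S1b", "DYS449", "DYS518", "DYS570", "DYS576", "DYS627"}
)

#: Markers amplifying two loci; every other marker has copy count 1.
MULTI_COPY_MARKERS = frozenset({"DYS385", "DYF387S1"})


@dataclass(frozen=True)
class Locus:
    """One marker of a panel."""

    name: str
    copy_count: int = 1
    rapidly_mutating: bool = False

    @property
    def series(self) -> tuple[str, ...]:
        """Allelic series this marker expands to ("a"/"b" suffix if copy-2)."""
        if self.copy_count == 2:
            return (self.name + "a", self.name + "b")
        return (self.name,)


# Marker order follows the multiplex kit documentation; the first 16 markers
# (17 series) form the original 17-plex, the rest are the 10 added series.
_YFILER17_MARKERS = [
    ("DYS19", 1),
    ("DYS385", 2),
    ("DYS389I", 1),
    ("DYS389II", 1),
    ("DYS390", 1),
    ("DYS391", 1),
    ("DYS392", 1),
    ("DYS393", 1),
    ("DYS437", 1),
    ("DYS438", 1),
    ("DYS439", 1),
    ("DYS448", 1),
    ("DYS456", 1),
    ("DYS458", 1),
    ("DYS635", 1),
    ("YGATAH4", 1),
]

_YFILER_PLUS_EXTRA_MARKERS = [
    ("DYS460", 1),
    ("DYS481", 1),
    ("DYS533", 1),
    ("DYF387S1", 2),
    ("DYS449", 1),
    ("DYS518", 1),
    ("DYS570", 1),
    ("DYS576", 1),
    ("DYS627", 1),
]


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of Y-STR markers defining an analysis panel.

    Parameters
    ----------
    name:
        Text label, e.g. ``"YFILER17"``.
    loci:
        Ordered marker records.
    dys389_converted:
        True once DYS389II has been replaced by the derived DYS389b series
        (DYS389II repeat count minus DYS389I).  Raw genotype tables use
        DYS389II; all statistics use DYS389b.
    """

    name: str
    loci: tuple[Locus, ...]
    dys389_converted: bool = False

    @property
    def series(self) -> tuple[str, ...]:
        """All allelic series in panel order, multi-copy markers expanded."""
        out: list[str] = []
        for locus in self.loci:
            out.extend(locus.series)
        return tuple(out)

    @property
    def size(self) -> int:
        return len(self.series)

    @property
    def rm_series(self) -> tuple[str, ...]:
        return tuple(s for s in self.series if s in RM_SERIES)

    def marker(self, name: str) -> Locus:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(f"marker {name!r} not in panel {self.name}")

    def is_subset_of(self, other: "PanelDefinition") -> bool:
        return set(self.series) <= set(other.series)

    def with_dys389b(self) -> "PanelDefinition":
        """Return the panel with DYS389II replaced by DYS389b."""
        if self.dys389_converted:
            return self
        loci = tuple(
            Locus("DYS389b", 1, l.rapidly_mutating) if l.name == "DYS389II" else l
            for l in self.loci
        )
        return PanelDefinition(self.name, loci, dys389_converted=True)


def _build(name: str, markers) -> PanelDefinition:
    loci = tuple(
        Locus(m, c, rapidly_mutating=any(s in RM_SERIES for s in Locus(m, c).series))
        for m, c in markers
    )
    return PanelDefinition(name, loci)


def yfiler17(dys389b: bool = True) -> PanelDefinition:
    """The original 17-series panel (16 markers, DYS385 double)."""
    p = _build("YFILER17", _YFILER17_MARKERS)
    return p.with_dys389b() if dys389b else p


def yfiler_plus27(dys389b: bool = True) -> PanelDefinition:
    """The 27-series panel: the 17 core series plus 10 added series
    including the seven rapidly mutating ones."""
    p = _build("YFILERPLUS27", _YFILER17_MARKERS + _YFILER_PLUS_EXTRA_MARKERS)
    return p.with_dys389b() if dys389b else p


def read_panel(path) -> PanelDefinition:
    """Load a panel from a YAML document.

    Expected layout::

        name: MYPANEL
        loci:
          - {name: DYS19, copy_count: 1, rm: false}
          - {name: DYS385, copy_count: 2}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    loci = tuple(
        Locus(rec["name"], int(rec.get("copy_count", 1)), bool(rec.get("rm", False)))
        for rec in doc["loci"]
    )
    return PanelDefinition(str(doc["name"]), loci, bool(doc.get("dys389_converted", False)))
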