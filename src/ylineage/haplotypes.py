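"""Haplotype data model, genotype-table I/O, locus-convention transforms,
missingness filtering and qPCR quality control.

Alleles are repeat counts stored as floats (intermediate alleles such as
13.2 are legal); ``None`` encodes a missing call.  A duplicated single-copy
locus (two peaks at a one-copy marker) is recorded with both observed
alleles but treated as missing by every downstream comparison — the
conservative forensic convention when no scoring rule is defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .panels import MULTI_COPY_MARKERS, PanelDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "Haplotype",
    "QcRecord",
    "read_haplotype_table",
    "load_genotypes",
    "write_haplotype_table",
    "convert_dys389",
    "apply_dys389b",
    "split_multicopy",
    "filter_by_missing",
    "compute_qc",
    "format_allele",
    "parse_allele",
]


@dataclass
class Haplotype:
    """Per-series allele calls for one male individual.

    ``calls`` maps every series of the active panel to a repeat count or
    ``None``.  ``duplication_flags`` maps single-copy loci at which two
    alleles were observed to the observed pair; such loci are ``None`` in
    ``calls``.
    """

    sample_id: str
    population: str
    calls: dict[str, float | None]
    stratum: str | None = None
    duplication_flags: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_typed(self) -> int:
        return sum(1 for v in self.calls.values() if v is not None)

    def n_missing(self, panel: PanelDefinition) -> int:
        return panel.size - self.n_typed

    def typed_series(self) -> set[str]:
        return {s for s, v in self.calls.items() if v is not None}

    def project(self, panel: PanelDefinition) -> "Haplotype":
        """Restrict the call map to the series of ``panel``."""
        calls = {s: self.calls.get(s) for s in panel.series}
        return replace(self, calls=calls)


@dataclass
class QcRecord:
    """qPCR quantification summary for one extract.

    ``degradation_index`` (small-target / large-target concentration) is
    kept at full precision; ``di_reported`` rounds it to the nearest
    integer for report output.  ``None`` means undefined (large target
    not detected).
    """

    sample_id: str
    small_target: float
    large_target: float | None
    y_target: float | None
    n_typed: int = 0

    @property
    def degradation_index(self) -> float | None:
        if self.large_target is None or self.large_target <= 0:
            return None
        return self.small_target / self.large_target

    @property
    def di_reported(self) -> int | None:
        di = self.degradation_index
        return None if di is None else int(round(di))


def compute_qc(
    sample_id: str,
    small_target: float,
    large_target: float | None,
    y_target: float | None = None,
    n_typed: int = 0,
) -> QcRecord:
    """Build a :class:`QcRecord`, validating concentrations."""
    for label, value in (
        ("small_target", small_target),
        ("large_target", large_target),
        ("y_target", y_target),
    ):
        if value is not None and value < 0:
            raise ValueError(f"negative concentration for {label}: {value}")
    return QcRecord(sample_id, small_target, large_target, y_target, n_typed)


# ---------------------------------------------------------------------------
# allele parsing / formatting


def parse_allele(cell: str) -> float | None:
    """Parse one allele cell; empty, "NA" and unparseable cells → missing."""
    text = str(cell).strip()
    if text == "" or text.upper() in {"NA", "N.D.", "ND", "NAN", "NEG", "MISSING"}:
        return None
    try:
        return float(text)
    except ValueError:
        logger.warning("unparseable allele cell %r treated as missing", cell)
        return None


def format_allele(value: float | None) -> str:
    """Format a repeat count with at most one fractional digit."""
    if value is None:
        return ""
    if math.isclose(value, round(value)):
        return str(int(round(value)))
    return f"{value:.1f}"


# ---------------------------------------------------------------------------
# locus-convention transforms


def convert_dys389(dys389I: float | None, dys389II: float | None) -> float | None:
    """DYS389b = DYS389II − DYS389I.

    DYS389II is amplified as a compound repeat containing DYS389I, so the
    independent allelic series is the difference.  Missing input propagates;
    a non-positive difference is flagged as an inconsistency and returns
    missing.
    """
    if dys389I is None or dys389II is None:
        return None
    if dys389II <= dys389I:
        logger.warning(
            "inconsistent DYS389 pair (I=%s, II=%s): DYS389b set missing",
            dys389I,
            dys389II,
        )
        return None
    return dys389II - dys389I


def apply_dys389b(
    haps: list[Haplotype], panel: PanelDefinition
) -> tuple[list[Haplotype], PanelDefinition]:
    """Replace the DYS389II series by DYS389b across a table."""
    if panel.dys389_converted:
        return haps, panel
    new_panel = panel.with_dys389b()
    out = []
    for h in haps:
        calls = dict(h.calls)
        b = convert_dys389(calls.get("DYS389I"), calls.pop("DYS389II", None))
        ordered = {s: (b if s == "DYS389b" else calls.get(s)) for s in new_panel.series}
        out.append(replace(h, calls=ordered))
    return out, new_panel


def split_multicopy(
    raw_calls: dict[str, list[float]], panel: PanelDefinition
) -> dict[str, float | None]:
    """Expand per-marker allele multisets into sorted per-series calls.

    Copy-2 markers: two values are sorted ascending onto the "a" (smaller)
    and "b" (larger) series; a single value is taken as homoallelic and
    assigned to both; no value leaves both missing.  More than two values
    at a copy-2 marker is not modelled and raises.
    """
    out: dict[str, float | None] = {}
    for locus in panel.loci:
        values = sorted(raw_calls.get(locus.name, []))
        if locus.copy_count == 2:
            if len(values) > 2:
                raise ValueError(
                    f">2 alleles at copy-2 marker {locus.name}: {values}"
                )
            if not values:
                a = b = None
            elif len(values) == 1:
                a = b = values[0]
            else:
                a, b = values
            sa, sb = locus.series
            out[sa], out[sb] = a, b
        else:
            # single-copy markers: >1 value is a duplication, handled by the
            # reader; here only 0/1 values are expected
            out[locus.series[0]] = values[0] if values else None
    return out


# ---------------------------------------------------------------------------
# table I/O


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_genotypes(
    path, panel: PanelDefinition
) -> tuple[list["Haplotype"], PanelDefinition]:
    """Read a genotype table and return it in DYS389b nomenclature.

    Accepts tables in either the raw (DYS389II) or converted (DYS389b)
    convention: the header decides, and raw tables are converted on the
    fly.
    """
    with open(path) as fh:
        header = fh.readline()
    columns = {c.strip() for c in header.split(_sniff_sep(path))}
    if "DYS389b" in columns:
        panel = panel.with_dys389b()
        return read_haplotype_table(path, panel), panel
    haps = read_haplotype_table(path, panel)
    return apply_dys389b(haps, panel)


def read_haplotype_table(path, panel: PanelDefinition) -> list[Haplotype]:
    """Read a delimiter-separated genotype table (one row per individual).

    The header must name ``sample_id`` and ``population`` plus locus
    columns; ``stratum`` is optional.  Copy-2 markers may appear either as
    two columns (``DYS385a``/``DYS385b``) or as one column holding
    comma-separated alleles.  A comma-separated cell at a single-copy locus
    records a duplication: both alleles are kept in
    ``duplication_flags`` and the series is missing downstream.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("genotype table lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id values: {dupes}")
    if "population" not in df.columns:
        raise ValueError("genotype table lacks a population column")

    meta_cols = {"sample_id", "population", "stratum"}
    marker_names = {l.name for l in panel.loci}
    series_names = set(panel.series)
    for col in df.columns:
        if col in meta_cols:
            continue
        if col not in marker_names and col not in series_names:
            raise ValueError(
                f"locus column {col!r} is not defined by panel {panel.name}"
            )

    haps: list[Haplotype] = []
    for _, row in df.iterrows():
        raw: dict[str, list[float]] = {}
        dup_flags: dict[str, tuple[float, float]] = {}
        for locus in panel.loci:
            values: list[float] = []
            if locus.copy_count == 2 and all(s in df.columns for s in locus.series):
                for s in locus.series:
                    v = parse_allele(row[s])
                    if v is not None:
                        values.append(v)
            elif locus.name in df.columns:
                cell = str(row[locus.name]).strip()
                parts = [p for p in cell.split(",") if p.strip() != ""]
                values = [v for p in parts if (v := parse_allele(p)) is not None]
            if locus.copy_count == 1 and len(values) > 1:
                if len(values) != 2:
                    raise ValueError(
                        f"{row['sample_id']}: >2 alleles at single-copy "
                        f"locus {locus.name}: {values}"
                    )
                dup_flags[locus.name] = tuple(sorted(values))  # type: ignore[assignment]
                logger.warning(
                    "%s: duplication at %s (alleles %s); locus excluded downstream",
                    row["sample_id"],
                    locus.name,
                    values,
                )
                values = []
            raw[locus.name] = values
        calls = split_multicopy(raw, panel)
        stratum = str(row["stratum"]).strip() if "stratum" in df.columns else None
        haps.append(
            Haplotype(
                sample_id=str(row["sample_id"]).strip(),
                population=str(row["population"]).strip(),
                stratum=stratum or None,
                calls=calls,
                duplication_flags=dup_flags,
            )
        )
    return haps


def write_haplotype_table(haps: list[Haplotype], panel: PanelDefinition, path) -> None:
    """Write haplotypes as CSV; inverse of :func:`read_haplotype_table`.

    Duplication-flagged loci are written back as comma-joined allele pairs
    so that a round trip reproduces both the flag and the missing call.
    """
    records = []
    for h in haps:
        rec: dict[str, str] = {"sample_id": h.sample_id, "population": h.population}
        if any(x.stratum for x in haps):
            rec["stratum"] = h.stratum or ""
        for s in panel.series:
            marker = s[:-1] if s[:-1] in MULTI_COPY_MARKERS else s
            if marker in h.duplication_flags:
                a, b = h.duplication_flags[marker]
                rec[s] = f"{format_allele(a)},{format_allele(b)}"
            else:
                rec[s] = format_allele(h.calls.get(s))
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def filter_by_missing(
    haps: list[Haplotype], panel: PanelDefinition, max_missing: int
) -> list[Haplotype]:
    """Keep haplotypes with at most ``max_missing`` untyped panel series.

    Order-preserving and idempotent; monotone in ``max_missing``.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    return [h for h in haps if h.n_missing(panel) <= max_missing]
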