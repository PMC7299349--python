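"""Readers and writers for the package's file formats.

Tabular formats are plain CSV/TSV handled through pandas; coverage is
bedGraph (0-based half-open, converted to the package's 1-based
inclusive coordinates at this boundary); gene models are GFF3; mutation
tables come either as a flat TSV or as a documented subset of the
GenomeDiff (GD) format produced by resequencing pipelines (SNP, DEL,
INS, MOB and AMP records). Truth sidecars for synthetic data are TOML.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnv import CoverageTrack
from .fitness import CompetitionAssay, PlateCount
from .growth import GrowthFit, ODCurve
from .insertions import InsertionEvent, SiteCatalog
from .parallelism import GeneLink, MutationRecord
from .viability import CellRecord

__all__ = [
    "read_od_csv",
    "write_od_csv",
    "write_fits_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_mutations_tsv",
    "write_mutations_tsv",
    "parse_genomediff",
    "GeneModels",
    "read_gff3_genes",
    "annotate_mutation",
    "read_insertions_tsv",
    "write_insertions_tsv",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "read_cells_tsv",
    "write_cells_tsv",
    "dump_toml",
]


# ---------------------------------------------------------------- OD curves

OD_COLUMNS = ["sample_id", "well_id", "medium", "time_h", "od420"]


def read_od_csv(path: str | Path) -> list[ODCurve]:
    """Long-format OD reader: one row per observation, one curve per well."""
    df = pd.read_csv(path, comment="#")
    missing = set(OD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    curves = []
    for (sample, well, medium), grp in df.groupby(
        ["sample_id", "well_id", "medium"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            ODCurve(
                sample_id=str(sample),
                well_id=str(well),
                medium=str(medium),
                times=grp["time_h"].to_numpy(dtype=float),
                od=grp["od420"].to_numpy(dtype=float),
            )
        )
    return curves


def write_od_csv(curves: Sequence[ODCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append((c.sample_id, c.well_id, c.medium, t, od))
    pd.DataFrame(rows, columns=OD_COLUMNS).to_csv(path, index=False)


def write_fits_csv(fits: dict[str, GrowthFit], path: str | Path) -> None:
    rows = [
        {
            "sample_id": sid,
            "r_glucose": f.r_glucose,
            "r_citrate": f.r_citrate,
            "lag_h": f.lag_h,
            "n_points_glucose": f.n_points_glucose,
            "n_points_citrate": f.n_points_citrate,
        }
        for sid, f in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------ colony counts

COUNT_COLUMNS = [
    "replicate_id",
    "competitor_id",
    "role",
    "timepoint",
    "dilution_factor",
    "volume_ml",
    "colonies",
]


def read_counts_csv(
    path: str | Path,
    duration_days: int = 1,
    transfer_dilution: float = 100.0,
    marker: Optional[dict[str, str]] = None,
) -> list[CompetitionAssay]:
    """Read competition plate counts into one assay per replicate.

    ``role`` is "test" or "reference"; ``timepoint`` is "initial" or
    "final". ``marker`` optionally maps competitor_id to its Ara marker
    state (defaults to "Ara+" for test, "Ara-" for reference).
    """
    df = pd.read_csv(path, comment="#")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    default_marker = {"test": "Ara+", "reference": "Ara-"}
    assays = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        points: dict[str, dict[str, list[PlateCount]]] = {
            "initial": {"test": [], "reference": []},
            "final": {"test": [], "reference": []},
        }
        for _, row in grp.iterrows():
            mk = (
                marker.get(str(row["competitor_id"]))
                if marker
                else default_marker[row["role"]]
            )
            points[row["timepoint"]][row["role"]].append(
                PlateCount(
                    competitor_id=str(row["competitor_id"]),
                    marker=mk or "Ara+",
                    dilution_factor=float(row["dilution_factor"]),
                    volume_ml=float(row["volume_ml"]),
                    colonies=int(row["colonies"]),
                )
            )
        assays.append(
            CompetitionAssay(
                replicate_id=str(rep),
                duration_days=duration_days,
                transfer_dilution=transfer_dilution,
                initial=points["initial"],
                final=points["final"],
            )
        )
    return assays


def write_counts_csv(rows: pd.DataFrame, path: str | Path) -> None:
    rows[COUNT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------- mutation tables

MUTATION_COLUMNS = [
    "clone_id",
    "treatment",
    "position",
    "type",
    "element",
    "genes_affected",
]


def _encode_links(links: Sequence[GeneLink]) -> str:
    parts = []
    for ln in links:
        d = "" if ln.distance_bp is None else str(ln.distance_bp)
        parts.append(f"{ln.gene}:{ln.relation}:{d}")
    return ";".join(parts)


def _decode_links(text: str) -> tuple[GeneLink, ...]:
    if not isinstance(text, str) or not text:
        return ()
    links = []
    for part in text.split(";"):
        gene, relation, dist = part.split(":")
        links.append(
            GeneLink(gene=gene, relation=relation,
                     distance_bp=int(dist) if dist else None)
        )
    return tuple(links)


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    """Flat mutation table; genes_affected encoded ``gene:relation:dist;...``."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        MutationRecord(
            clone_id=str(r["clone_id"]),
            treatment=str(r["treatment"]),
            position=int(r["position"]),
            type=str(r["type"]),
            element=str(r["element"]),
            genes_affected=_decode_links(r["genes_affected"]),
        )
        for _, r in df.iterrows()
    ]


def write_mutations_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "clone_id": r.clone_id,
            "treatment": r.treatment,
            "position": r.position,
            "type": r.type,
            "element": r.element,
            "genes_affected": _encode_links(r.genes_affected),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


_GD_SNP_TYPES = {
    "nonsynonymous": "snp_nonsynonymous",
    "synonymous": "snp_synonymous",
    "nonsense": "snp_nonsense",
    "intergenic": "snp_intergenic",
    "noncoding": "snp_intergenic",
}


def parse_genomediff(
    path: str | Path, clone_id: str, treatment: str
) -> list[MutationRecord]:
    """Parse a documented subset of the GenomeDiff mutation format.

    SNP, DEL, INS, MOB and AMP records are read; evidence and metadata
    lines are ignored. SNPs require a ``snp_type=`` field to be typed;
    gene annotations are taken from ``gene_name=`` when present
    (intergenic gene_name values like ``geneA/geneB`` give no single
    assignment and are left unannotated).
    """
    records: list[MutationRecord] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind not in ("SNP", "DEL", "INS", "MOB", "AMP"):
            continue
        position = int(fields[4])
        kv = {}
        for f in fields[5:]:
            if "=" in f:
                key, _, val = f.partition("=")
                kv[key] = val
        if kind == "SNP":
            mtype = _GD_SNP_TYPES.get(kv.get("snp_type", ""), "snp_intergenic")
            element = ""
        elif kind == "DEL":
            mtype, element = "deletion", ""
        elif kind == "INS":
            mtype, element = "indel", ""
        elif kind == "AMP":
            mtype, element = "duplication_amplification", ""
        else:  # MOB
            mtype, element = "is_insertion", fields[5] if len(fields) > 5 else "IS"
        links: tuple[GeneLink, ...] = ()
        gene_name = kv.get("gene_name", "")
        if gene_name and "/" not in gene_name and "," not in gene_name:
            relation = "promoter" if "gene_position" in kv and kv[
                "gene_position"
            ].startswith("-") else "coding"
            dist = None
            if relation == "promoter":
                try:
                    dist = abs(int(kv["gene_position"]))
                except ValueError:
                    dist = None
            links = (GeneLink(gene=gene_name, relation=relation, distance_bp=dist),)
        records.append(
            MutationRecord(
                clone_id=clone_id,
                treatment=treatment,
                position=position,
                type=mtype,
                element=element or ("IS" if mtype == "is_insertion" else ""),
                genes_affected=links,
            )
        )
    return records


# ---------------------------------------------------------------- gene models


class GeneModels:
    """Gene coordinates from a GFF3 file, queryable by position.

    Coordinates are GFF3's native 1-based inclusive. Only ``gene``
    features are retained; the gene name comes from the Name= attribute
    (falling back to ID=).
    """

    def __init__(self, genes: pd.DataFrame):
        required = {"gene", "start", "end", "strand"}
        if not required <= set(genes.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        self.genes = genes.reset_index(drop=True)
        self._tree = IntervalTree()
        for idx, row in self.genes.iterrows():
            self._tree[row["start"] : row["end"] + 1] = idx

    def overlapping(self, start: int, end: int) -> pd.DataFrame:
        idx = sorted(iv.data for iv in self._tree.overlap(start, end + 1))
        return self.genes.iloc[idx]

    def promoter_candidates(self, pos: int, window_bp: int) -> list[tuple[str, int]]:
        """Genes whose promoter region (within window upstream) covers pos."""
        out = []
        for _, g in self.genes.iterrows():
            if g["strand"] == "+" and g["start"] - window_bp <= pos < g["start"]:
                out.append((g["gene"], int(g["start"] - pos)))
            elif g["strand"] == "-" and g["end"] < pos <= g["end"] + window_bp:
                out.append((g["gene"], int(pos - g["end"])))
        return out


def read_gff3_genes(path: str | Path) -> GeneModels:
    """Load gene features from GFF3 (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = [
        {
            "gene": (g.attributes.get("Name") or g.attributes.get("ID") or [""])[0],
            "seqid": g.seqid,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for g in db.features_of_type("gene")
    ]
    return GeneModels(
        pd.DataFrame(rows, columns=["gene", "seqid", "start", "end", "strand"])
    )


def annotate_mutation(
    record: MutationRecord,
    models: GeneModels,
    span_bp: int = 1,
    promoter_window_bp: int = 150,
) -> MutationRecord:
    """Attach gene links to a mutation from gene models.

    The mutation occupies [position, position + span_bp - 1]. Genes it
    overlaps get coding links; when it overlaps none, genes whose
    upstream promoter window covers the position get promoter links with
    their distances.
    """
    start, end = record.position, record.position + span_bp - 1
    hits = models.overlapping(start, end)
    links: list[GeneLink] = []
    if len(hits):
        for _, g in hits.iterrows():
            spans = start < g["start"] and end > g["end"]
            relation = "spanning" if spans else "coding"
            links.append(GeneLink(gene=g["gene"], relation=relation))
    else:
        for gene, dist in models.promoter_candidates(record.position, promoter_window_bp):
            links.append(GeneLink(gene=gene, relation="promoter", distance_bp=dist))
    return MutationRecord(
        clone_id=record.clone_id,
        treatment=record.treatment,
        position=record.position,
        type=record.type,
        element=record.element,
        genes_affected=tuple(links),
    )


# ----------------------------------------------------------- insertion events

INSERTION_COLUMNS = ["clone_id", "treatment", "element", "position", "gene", "relation"]


def read_insertions_tsv(path: str | Path) -> list[InsertionEvent]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    missing = set(INSERTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        InsertionEvent(
            clone_id=str(r["clone_id"]),
            treatment=str(r["treatment"]),
            element=str(r["element"]),
            site=int(r["position"]),
            gene_label=str(r["gene"]),
            relation=str(r["relation"]),
        )
        for _, r in df.iterrows()
    ]


def write_insertions_tsv(events: Sequence[InsertionEvent], path: str | Path) -> None:
    rows = [
        {
            "clone_id": e.clone_id,
            "treatment": e.treatment,
            "element": e.element,
            "position": e.site,
            "gene": e.gene_label,
            "relation": e.relation,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=INSERTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> SiteCatalog:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"position", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: catalog needs 'position' and 'weight' columns")
    df = df.sort_values("position")
    return SiteCatalog(
        sites=tuple(int(p) for p in df["position"]),
        weights=tuple(int(w) for w in df["weight"]),
    )


def write_catalog_tsv(catalog: SiteCatalog, path: str | Path) -> None:
    pd.DataFrame({"position": catalog.sites, "weight": catalog.weights}).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------- coverage


def read_bedgraph(path: str | Path, genome_id: str = "") -> CoverageTrack:
    """Read per-position depth from bedGraph (0-based half-open intervals).

    The genome length is taken as the largest end coordinate; positions
    not covered by any interval get depth 0.
    """
    starts, ends, values = [], [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, s, e, v = line.split("\t")[:4]
        starts.append(int(s))
        ends.append(int(e))
        values.append(int(float(v)))
        if not genome_id:
            genome_id = chrom
    if not starts:
        raise ValueError(f"{path}: empty bedGraph")
    length = max(ends)
    depth = np.zeros(length, dtype=int)
    for s, e, v in zip(starts, ends, values):
        depth[s:e] = v  # 0-based half-open -> array slice, exact round trip
    return CoverageTrack(genome_id=genome_id, depth=depth)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write depth as run-length-encoded bedGraph (0-based half-open)."""
    d = track.depth
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [d.size]])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for s, e in zip(starts, ends):
            w.writerow([track.genome_id or "genome", int(s), int(e), int(d[s])])


# -------------------------------------------------------------------- cells

CELL_COLUMNS = ["replicate_id", "region_score", "green", "red"]


def read_cells_tsv(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        CellRecord(
            replicate_id=str(r["replicate_id"]),
            region_score=float(r["region_score"]),
            green=float(r["green"]),
            red=float(r["red"]),
        )
        for _, r in df.iterrows()
    ]


def write_cells_tsv(cells: Sequence[CellRecord], path: str | Path) -> None:
    rows = [
        {"replicate_id": c.replicate_id, "region_score": c.region_score,
         "green": c.green, "red": c.red}
        for c in cells
    ]
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- TOML


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(data: dict, path: str | Path) -> None:
    """Write a (possibly nested) dict of scalars/lists as TOML.

    Covers what truth sidecars need; read back with ``tomllib``.
    """
    lines: list[str] = []

    def emit(table: dict, prefix: str) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix and scalars:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        for k, v in subtables.items():
            lines.append("")
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(data, "")
    Path(path).write_text("\n".join(lines) + "\n")
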