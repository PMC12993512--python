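"""Readers and writers for count tables, taxonomy, metadata and networks.

Formats: TSV taxa x samples count matrices, a BIOM-v1-compatible JSON
variant, two-column taxonomy TSV (id, semicolon-delimited lineage),
sample metadata TSV, GraphML and edge-list TSV for networks.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, CooccurrenceNetwork, SampleMetadata, TaxonRecord

# 18S lineages are split into phototrophs and fungi by keyword; the map is
# module-level and editable so new clades can be added without code changes.
FUNGAL_KEYWORDS = (
    "Chytridiomycota",
    "Cryptomycota",
    "Zoopagomycota",
    "Dikarya",
    "Ascomycota",
    "Basidiomycota",
    "Fungi",
)
PHOTOTROPH_KEYWORDS = (
    "Chlorophyta",
    "Chlorophyceae",
    "Charophyta",
    "Phragmoplastophyta",
    "Cryptomonadales",
    "Ochrophyta",
    "Diatomea",
    "Chrysophyceae",
    "Xanthophyceae",
)
# Non-bacterial 16S reads (organelles, archaea) are dropped at read time.
NONBACTERIAL_16S_KEYWORDS = ("Archaea", "Chloroplast", "Mitochondria")


class TableFormatError(ValueError):
    """Raised for malformed count-table files."""


def assign_domain(lineage: tuple[str, ...], marker: str) -> str:
    """Deterministic keyword-based domain label for one lineage."""
    if marker == "16S":
        return "bacteria"
    joined = ";".join(lineage)
    for kw in FUNGAL_KEYWORDS:
        if kw.lower() in joined.lower():
            return "fungus"
    for kw in PHOTOTROPH_KEYWORDS:
        if kw.lower() in joined.lower():
            return "phototroph"
    return "unknown"


def _family_from_lineage(lineage: tuple[str, ...]) -> str:
    if len(lineage) >= 5 and lineage[4].strip():
        return lineage[4].strip()
    return "unclassified"


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column TSV: taxon id, semicolon-delimited lineage."""
    out: dict[str, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise TableFormatError(f"taxonomy line lacks two columns: {line!r}")
        out[parts[0]] = tuple(s.strip() for s in parts[1].split(";"))
    return out


def read_abundance_table(
    path: str | Path,
    marker: str,
    taxonomy_path: str | Path,
) -> AbundanceTable:
    """Read a taxa x samples TSV count matrix with taxonomy annotations.

    18S taxa are labelled phototroph or fungus from lineage keywords;
    unmatched lineages are labelled ``unknown`` (kept, reported by callers).
    Non-bacterial 16S taxa (archaea, chloroplast, mitochondria) are dropped.
    Taxa missing from the taxonomy file are labelled ``unknown``; for 16S
    they are retained as bacteria with an empty lineage.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise TableFormatError(f"{path}: empty count table")
    lines = text.splitlines()
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise TableFormatError(f"{path}: header has no sample columns")
    n_cols = len(header)
    taxonomy = read_taxonomy(taxonomy_path)

    ids: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != n_cols:
            raise TableFormatError(
                f"{path}: ragged row {parts[0]!r} "
                f"({len(parts)} fields, expected {n_cols})"
            )
        ids.append(parts[0])
        try:
            rows.append([int(float(v)) for v in parts[1:]])
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric count in row "
                                   f"{parts[0]!r}") from exc

    taxa: list[TaxonRecord] = []
    keep_rows: list[int] = []
    for i, tid in enumerate(ids):
        lineage = taxonomy.get(tid, ())
        joined = ";".join(lineage)
        if marker == "16S":
            if any(kw.lower() in joined.lower() for kw in NONBACTERIAL_16S_KEYWORDS):
                continue  # organelles / archaea never enter the analysis
            domain = "bacteria"
        else:
            domain = assign_domain(lineage, marker)
        taxa.append(
            TaxonRecord(tid, domain, lineage, _family_from_lineage(lineage))
        )
        keep_rows.append(i)
    counts = np.asarray([rows[i] for i in keep_rows], dtype=np.int64)
    if counts.size == 0:
        counts = counts.reshape(0, len(sample_ids))
    return AbundanceTable(counts, taxa, sample_ids, marker)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def write_taxonomy(table: AbundanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in table.taxa:
            fh.write(f"{t.taxon_id}\t{';'.join(t.lineage)}\n")


# -- BIOM-compatible JSON (v1.0 sparse) ------------------------------------

def write_biom_json(table: AbundanceTable, path: str | Path) -> None:
    """Minimal BIOM v1.0 sparse OTU table."""
    data = [
        [int(i), int(j), int(v)]
        for (i, j), v in np.ndenumerate(table.counts)
        if v != 0
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "coocnet",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(table.shape),
        "rows": [
            {
                "id": t.taxon_id,
                "metadata": {
                    "taxonomy": list(t.lineage),
                    "domain_label": t.domain_label,
                    "marker": table.marker,
                },
            }
            for t in table.taxa
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def read_biom_json(path: str | Path) -> AbundanceTable:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["shape"])
    counts = np.zeros(shape, dtype=np.int64)
    for i, j, v in doc["data"]:
        counts[i, j] = v
    marker = doc["rows"][0]["metadata"].get("marker", "16S") if doc["rows"] else "16S"
    taxa = [
        TaxonRecord(
            r["id"],
            r["metadata"].get("domain_label", "unknown"),
            tuple(r["metadata"].get("taxonomy", [])),
            _family_from_lineage(tuple(r["metadata"].get("taxonomy", []))),
        )
        for r in doc["rows"]
    ]
    return AbundanceTable(counts, taxa, [c["id"] for c in doc["columns"]], marker)


# -- metadata ---------------------------------------------------------------

_CATEGORICAL = {"floodplain", "stream_type", "deglaciation",
                "consistent_categorisation"}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise TableFormatError("metadata must have a sample_id column")
    out = []
    for _, row in df.iterrows():
        env = {
            c: float(row[c])
            for c in df.columns
            if c not in _CATEGORICAL and c != "sample_id"
            and not (isinstance(row[c], float) and math.isnan(row[c]))
        }
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                floodplain=str(row.get("floodplain", "NA")),
                stream_type=str(row["stream_type"]),
                deglaciation=str(row["deglaciation"]),
                environment=env,
                consistent_categorisation=bool(
                    row.get("consistent_categorisation", True)
                ),
            )
        )
    return out


def write_metadata(meta: list[SampleMetadata], path: str | Path) -> None:
    from .datatypes import metadata_frame

    metadata_frame(meta).to_csv(path, sep="\t")


def pair_samples(
    t16: AbundanceTable,
    t18: AbundanceTable,
    meta: list[SampleMetadata],
) -> tuple[AbundanceTable, AbundanceTable]:
    """Restrict both tables to samples with paired 16S+18S data.

    Only samples present in both tables AND categorised consistently across
    the two sampling campaigns (metadata flag) are kept; the returned tables
    have identical column order.
    """
    if t16.n_samples == 0 or t18.n_samples == 0:
        raise ValueError("cannot pair an empty table")
    consistent = {
        m.sample_id for m in meta if m.consistent_categorisation
    }
    shared = [
        s for s in t16.sample_ids if s in set(t18.sample_ids) and s in consistent
    ]
    if not shared:
        only16 = sorted(set(t16.sample_ids) - set(t18.sample_ids))
        only18 = sorted(set(t18.sample_ids) - set(t16.sample_ids))
        raise ValueError(
            "no paired samples after consistency filtering; "
            f"16S-only: {only16}; 18S-only: {only18}"
        )
    return t16.select_samples(shared), t18.select_samples(shared)


# -- networks ---------------------------------------------------------------

def write_network(
    net: CooccurrenceNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Write a network as GraphML or edge-list TSV (attributes preserved)."""
    net.validate()
    if format == "graphml":
        nx.write_graphml(net.graph, str(path))
    elif format == "edge_tsv":
        cols = [
            "source", "target", "support_count", "sparcc_rho",
            "spearman_rho", "mb_selected", "consensus_sign",
        ]
        rows = []
        for u, v, d in sorted(net.graph.edges(data=True)):
            rows.append({
                "source": u,
                "target": v,
                "support_count": d.get("support_count", 1),
                "sparcc_rho": d.get("sparcc_rho", float("nan")),
                "spearman_rho": d.get("spearman_rho", float("nan")),
                "mb_selected": int(d.get("mb_selected", 0)),
                "consensus_sign": d.get("consensus_sign", "+"),
            })
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> CooccurrenceNetwork:
    if format == "graphml":
        return CooccurrenceNetwork(nx.read_graphml(str(path)))
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, r in df.iterrows():
            g.add_edge(
                r["source"], r["target"],
                support_count=int(r["support_count"]),
                sparcc_rho=float(r["sparcc_rho"]),
                spearman_rho=float(r["spearman_rho"]),
                mb_selected=int(r["mb_selected"]),
                consensus_sign=str(r["consensus_sign"]),
            )
        return CooccurrenceNetwork(g)
    raise ValueError(f"unknown network format {format!r}")
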