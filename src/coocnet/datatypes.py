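"""Core data containers for the cross-domain co-occurrence pipeline.

The pipeline's substrate is a taxon-by-sample count table carrying domain
labels (bacteria / phototroph / fungus) and taxonomy, plus per-sample
metadata describing the floodplain, stream type (glacier-fed stream vs
tributary), deglaciation class and environmental measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DOMAIN_LABELS = ("bacteria", "phototroph", "fungus", "unknown")
MARKERS = ("16S", "18S")
N_LINEAGE_RANKS = 7


@dataclass
class TaxonRecord:
    """One ASV/OTU with its domain label and taxonomic lineage.

    ``lineage`` holds up to seven rank strings (Kingdom..Genus/species);
    missing trailing ranks are allowed. ``family`` is derived from the
    lineage (5th rank when present) and used for family-level aggregation.
    """

    taxon_id: str
    domain_label: str
    lineage: tuple[str, ...] = ()
    family: str = "unclassified"

    def __post_init__(self) -> None:
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(
                f"domain_label {self.domain_label!r} not in {DOMAIN_LABELS}"
            )


class AbundanceTable:
    """Taxon-by-sample read counts for one marker gene (16S or 18S).

    Counts are non-negative integers, taxa are rows and samples are
    columns (the amplicon convention). Tables are never rarefied.
    """

    def __init__(
        self,
        counts: np.ndarray | pd.DataFrame,
        taxa: list[TaxonRecord],
        sample_ids: list[str],
        marker: str,
    ) -> None:
        counts = np.asarray(
            counts.values if isinstance(counts, pd.DataFrame) else counts
        )
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples matrix")
        if np.any(counts < 0):
            raise ValueError("negative counts are not allowed")
        if counts.shape != (len(taxa), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxa)} taxa x {len(sample_ids)} samples"
            )
        if marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}")
        ids = [t.taxon_id for t in taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if marker == "16S" and any(t.domain_label != "bacteria" for t in taxa):
            raise ValueError("16S tables may only contain bacteria")
        if marker == "18S" and any(t.domain_label == "bacteria" for t in taxa):
            raise ValueError("18S tables may not contain bacteria")
        self.counts = counts.astype(np.int64)
        self.taxa = list(taxa)
        self.sample_ids = list(sample_ids)
        self.marker = marker

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )

    def domain_of(self, taxon_id: str) -> str:
        return self._taxon_map()[taxon_id].domain_label

    def _taxon_map(self) -> dict[str, TaxonRecord]:
        return {t.taxon_id: t for t in self.taxa}

    def select_taxa(self, keep_ids: list[str]) -> "AbundanceTable":
        """Row subset preserving the given order."""
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        rows = [index[t] for t in keep_ids]
        return AbundanceTable(
            self.counts[rows, :],
            [self.taxa[i] for i in rows],
            self.sample_ids,
            self.marker,
        )

    def select_samples(self, keep_ids: list[str]) -> "AbundanceTable":
        """Column subset preserving the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep_ids]
        return AbundanceTable(
            self.counts[:, cols], self.taxa, list(keep_ids), self.marker
        )

    def __repr__(self) -> str:
        return (
            f"AbundanceTable(marker={self.marker}, "
            f"taxa={self.n_taxa}, samples={self.n_samples})"
        )


@dataclass
class SampleMetadata:
    """Per-sample study design factors and environmental measurements."""

    sample_id: str
    floodplain: str
    stream_type: str
    deglaciation: str
    environment: dict[str, float] = field(default_factory=dict)
    consistent_categorisation: bool = True

    _STREAM_TYPES = ("GFS", "TRIB")
    _DEGLACIATION = ("pre2000", "post2000")

    def __post_init__(self) -> None:
        if self.stream_type not in self._STREAM_TYPES:
            raise ValueError(f"stream_type must be one of {self._STREAM_TYPES}")
        if self.deglaciation not in self._DEGLACIATION:
            raise ValueError(
                f"deglaciation must be one of {self._DEGLACIATION}"
            )


def metadata_frame(meta: list[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of a metadata collection, env variables as columns."""
    rows = []
    for m in meta:
        row = {
            "sample_id": m.sample_id,
            "floodplain": m.floodplain,
            "stream_type": m.stream_type,
            "deglaciation": m.deglaciation,
            "consistent_categorisation": m.consistent_categorisation,
        }
        row.update(m.environment)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def stack_tables(t16: AbundanceTable, t18: AbundanceTable) -> AbundanceTable:
    """Stack paired 16S and 18S tables into one cross-domain table.

    Sample columns must already be aligned (see ``pair_samples``). The
    stacked table keeps the 18S marker slot unused and is tagged 16S for
    container validity only via a thin wrapper: we bypass the marker/domain
    consistency check by constructing through ``StackedTable``.
    """
    if t16.sample_ids != t18.sample_ids:
        raise ValueError("tables must be sample-aligned before stacking")
    return StackedTable(
        np.vstack([t16.counts, t18.counts]),
        t16.taxa + t18.taxa,
        t16.sample_ids,
    )


class StackedTable(AbundanceTable):
    """Cross-domain (16S + 18S) table; domain mixing is expected here."""

    def __init__(self, counts, taxa, sample_ids) -> None:
        # bypass the per-marker domain check: stacked tables mix domains
        self.counts = np.asarray(counts).astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        ids = [t.taxon_id for t in taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids across stacked tables")
        self.taxa = list(taxa)
        self.sample_ids = list(sample_ids)
        self.marker = "16S"  # container slot; not meaningful for stacks

    def select_taxa(self, keep_ids: list[str]) -> "StackedTable":
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        rows = [index[t] for t in keep_ids]
        return StackedTable(
            self.counts[rows, :], [self.taxa[i] for i in rows], self.sample_ids
        )

    def select_samples(self, keep_ids: list[str]) -> "StackedTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep_ids]
        return StackedTable(self.counts[:, cols], self.taxa, list(keep_ids))


def marker_block_indices(table: AbundanceTable) -> list[np.ndarray]:
    """Row-index groups per sequencing library (16S = bacteria, 18S = rest).

    Each marker gene is sequenced as its own library, so compositional
    treatment (closure, CLR, Dirichlet resampling) must happen within the
    marker block; cross-domain statistics then use the concatenated blocks.
    """
    is16 = np.array([t.domain_label == "bacteria" for t in table.taxa])
    blocks = []
    if is16.any():
        blocks.append(np.flatnonzero(is16))
    if (~is16).any():
        blocks.append(np.flatnonzero(~is16))
    return blocks


class CooccurrenceNetwork:
    """Undirected consensus network of positively co-occurring taxa.

    Wraps a simple :class:`networkx.Graph`. Node attributes carry the
    domain label and family; edge attributes carry per-method statistics
    (``sparcc_rho``, ``spearman_rho``, ``mb_selected``), the number of
    supporting methods (``support_count``) and the consensus sign
    (always ``+`` after positive-consensus filtering).
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.validate()

    def validate(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise ValueError("self-loops are not allowed")
        if isinstance(g, (nx.MultiGraph, nx.DiGraph)):
            raise ValueError("network must be a simple undirected graph")
        for _, _, d in g.edges(data=True):
            sign = d.get("consensus_sign", "+")
            if sign != "+":
                raise ValueError("consensus edges must be positive")
            sc = d.get("support_count", 1)
            if sc not in (1, 2, 3):
                raise ValueError("support_count must be 1, 2 or 3")

    @classmethod
    def from_edges(
        cls,
        nodes: dict[str, dict],
        edges: list[tuple[str, str, dict]],
    ) -> "CooccurrenceNetwork":
        g = nx.Graph()
        for node, attrs in nodes.items():
            g.add_node(node, **attrs)
        for u, v, attrs in edges:
            if u not in g or v not in g:
                raise ValueError(f"edge ({u}, {v}) references a missing node")
            g.add_edge(u, v, **attrs)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __repr__(self) -> str:
        return f"CooccurrenceNetwork(nodes={self.n_nodes}, edges={self.n_edges})"
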