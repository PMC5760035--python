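"""Core data containers shared by every pipeline stage.

The substrate of the analysis is a probe x sample matrix of log2
intensities together with per-probe detection p-values (the probability
that a probe's signal arises from array background) and sample metadata
(brain region, time after the last ethanol-vapor exposure, condition,
animal).  Everything downstream — detection filtering, differential
expression, temporal pairing — operates on :class:`ExpressionDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["region", "time_h", "condition", "animal_id"]
PROBE_COLUMNS = ["species", "maturity", "annotation"]

TREATED = "treated"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """Probe x sample expression matrix with detection p-values and metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Log2 intensities, indexed by probe_id, columns are sample_ids.
    detection_p : pandas.DataFrame
        Same shape/labels as ``values``; entries in [0, 1].
    samples : pandas.DataFrame
        Indexed by sample_id with columns region, time_h, condition,
        animal_id. Column order follows ``values``.
    probes : pandas.DataFrame
        Indexed by probe_id with columns species, maturity, annotation.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.probes.index):
            raise ValueError("values rows must match probes table")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns must match samples table")
        if self.detection_p.shape != self.values.shape:
            raise ValueError("detection_p shape must match values")
        if not self.detection_p.index.equals(self.values.index):
            raise ValueError("detection_p rows must match values")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        dp = self.detection_p.to_numpy()
        if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
            raise ValueError("detection p-values must lie in [0, 1]")

    # ------------------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def regions(self) -> list[str]:
        return sorted(self.samples["region"].unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        ids = [s for s in self.values.columns if s in set(sample_ids)]
        return ExpressionDataset(
            values=self.values[ids],
            detection_p=self.detection_p[ids],
            samples=self.samples.loc[ids],
            probes=self.probes,
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionDataset":
        keep = [p for p in self.values.index if p in set(probe_ids)]
        return ExpressionDataset(
            values=self.values.loc[keep],
            detection_p=self.detection_p.loc[keep],
            samples=self.samples,
            probes=self.probes.loc[keep],
        )

    def region(self, region: str) -> "ExpressionDataset":
        ids = self.samples.index[self.samples["region"] == region]
        return self.subset_samples(list(ids))

    def group_samples(self, region: str, time_h: int, condition: str) -> list[str]:
        m = self.samples
        sel = (m["region"] == region) & (m["time_h"] == time_h) & (m["condition"] == condition)
        return list(m.index[sel])

    # ------------------------------------------------------------------
    def to_tsv(self, prefix: str | Path) -> dict[str, Path]:
        """Write the expression / detection-p / metadata TSV trio."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "values": prefix.with_name(prefix.name + "_expr.tsv"),
            "detection_p": prefix.with_name(prefix.name + "_detp.tsv"),
            "samples": prefix.with_name(prefix.name + "_samples.tsv"),
            "probes": prefix.with_name(prefix.name + "_probes.tsv"),
        }
        self.values.to_csv(paths["values"], sep="\t", index_label="probe_id")
        self.detection_p.to_csv(paths["detection_p"], sep="\t", index_label="probe_id")
        self.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
        self.probes.to_csv(paths["probes"], sep="\t", index_label="probe_id")
        return paths

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "ExpressionDataset":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_name(prefix.name + "_expr.tsv"), sep="\t", index_col="probe_id")
        detp = pd.read_csv(prefix.with_name(prefix.name + "_detp.tsv"), sep="\t", index_col="probe_id")
        samples = pd.read_csv(prefix.with_name(prefix.name + "_samples.tsv"), sep="\t", index_col="sample_id")
        probes = pd.read_csv(prefix.with_name(prefix.name + "_probes.tsv"), sep="\t", index_col="probe_id")
        return cls(values=values, detection_p=detp, samples=samples, probes=probes)


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping emitted by the simulator.

    Serves as the oracle for recovery tests: which probes were shifted,
    which miRNA->gene regulations were planted (with their temporal lag),
    which knowledgebase molecules are hubs, and which samples were
    corrupted into outliers.
    """

    de_mirnas: set[tuple[str, str, int, float]] = field(default_factory=set)
    de_targets: set[tuple[str, str, int, float]] = field(default_factory=set)
    true_pairs: set[tuple[str, str, int, int]] = field(default_factory=set)
    planted_hubs: set[str] = field(default_factory=set)
    outlier_samples: set[str] = field(default_factory=set)

    def de_mirna_probes(self, region: str, time_h: int) -> set[str]:
        return {p for (p, r, t, _fc) in self.de_mirnas if r == region and t == time_h}

    def de_target_genes(self, region: str, time_h: int) -> set[str]:
        return {g for (g, r, t, _fc) in self.de_targets if r == region and t == time_h}

    def to_json_dict(self) -> dict:
        return {
            "de_mirnas": sorted([list(x) for x in self.de_mirnas]),
            "de_targets": sorted([list(x) for x in self.de_targets]),
            "true_pairs": sorted([list(x) for x in self.true_pairs]),
            "planted_hubs": sorted(self.planted_hubs),
            "outlier_samples": sorted(self.outlier_samples),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_mirnas={(a, b, int(c), float(f)) for a, b, c, f in d["de_mirnas"]},
            de_targets={(a, b, int(c), float(f)) for a, b, c, f in d["de_targets"]},
            true_pairs={(a, b, int(c), int(t)) for a, b, c, t in d["true_pairs"]},
            planted_hubs=set(d["planted_hubs"]),
            outlier_samples=set(d["outlier_samples"]),
        )


@dataclass(frozen=True)
class InteractionRecord:
    """One miRNA -> gene relation from the interaction table.

    ``evidence`` is "experimental", "predicted_high" or "predicted_low";
    ``context_score`` follows the target-prediction convention that more
    negative means a stronger predicted interaction.
    """

    mirna_id: str
    gene_id: str
    evidence: str
    mirna_conserved: bool
    n_conserved_sites: int
    context_score: float

    EVIDENCE_CLASSES = ("experimental", "predicted_high", "predicted_low")

    def __post_init__(self) -> None:
        if self.evidence not in self.EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.n_conserved_sites < 0:
            raise ValueError("n_conserved_sites must be >= 0")


def interactions_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "gene_id": r.gene_id,
            "evidence": r.evidence,
            "mirna_conserved": r.mirna_conserved,
            "n_conserved_sites": r.n_conserved_sites,
            "context_score": r.context_score,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence", "mirna_conserved", "n_conserved_sites", "context_score"])


def interactions_from_frame(df: pd.DataFrame) -> list[InteractionRecord]:
    return [
        InteractionRecord(
            mirna_id=row.mirna_id,
            gene_id=row.gene_id,
            evidence=row.evidence,
            mirna_conserved=bool(row.mirna_conserved),
            n_conserved_sites=int(row.n_conserved_sites),
            context_score=float(row.context_score),
        )
        for row in df.itertuples(index=False)
    ]
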