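"""Synthetic two-group microarray study generator.

Emulates the structure of a chronic-intermittent-ethanol time-course
experiment: three brain regions (AMY, NAC, PFC), three sacrifice times
(0, 8, 120 h after the last vapor exposure), 8 treated and 8 control
animals per group, a miRNA array and an mRNA array profiled from the
same animals.  Planted effects are small signed linear fold changes
(|FC| ~ 1.2-1.6 for miRNAs, 1.03-1.11 for their mRNA targets), with
target changes lagging their regulator miRNA's change, plus a
miRNA->gene interaction table containing decoys, a heavy-tailed
molecule-interaction knowledgebase with planted hubs, and cell-type
gene lists with one planted enrichment.

Every generator is a pure function of a :class:`SimulationConfig` and
its seed: identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .datasets import (
    CONTROL,
    TREATED,
    ExpressionDataset,
    GroundTruth,
    InteractionRecord,
)

# Background intensity model for detection p-values: a probe's signal is
# "detected" when it is improbable under the array-background
# distribution.  Log2 background ~ Normal(4, 1); probe baselines
# ~ Normal(7, 1.5), so weakly expressed probes genuinely fail the
# detection filter, as on real arrays.
BACKGROUND_MEAN = 4.0
BACKGROUND_SD = 1.0
BASELINE_MEAN = 7.0
BASELINE_SD = 1.5
# Planted effects are only placed on probes expressed clearly above
# background so the detection filter does not erase the ground truth.
PLANT_MIN_BASELINE = 6.0


def _default_lag_model() -> dict[int, tuple[int, ...]]:
    # miRNA change precedes target change: 0h regulators hit targets at
    # 8 and 120 h, 8h regulators at 120 h; 120h regulators can only pair
    # with same-time targets.
    return {0: (8, 120), 8: (120,), 120: (120,)}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the emulated design: 3 regions x 3 times x
    (8 treated + 8 control), small signed linear fold changes, opposite
    -sign miRNA->target regulation with a temporal lag.
    """

    seed: int = 0
    regions: tuple[str, ...] = ("AMY", "NAC", "PFC")
    times_h: tuple[int, ...] = (0, 8, 120)
    n_per_group: int = 8
    n_mirna_probes: int = 600
    n_mrna_probes: int = 2000
    n_de_mirna_per_time: int = 12
    n_targets_per_mirna: int = 4
    mirna_fc_range: tuple[float, float] = (1.2, 1.6)
    mrna_fc_range: tuple[float, float] = (1.03, 1.11)
    lag_model: dict[int, tuple[int, ...]] = field(default_factory=_default_lag_model)
    same_sign_fraction: float = 0.0
    noise_sd: float = 0.04
    n_outlier_samples: int = 2
    decoy_interaction_fraction: float = 0.5
    kb_n_molecules: int = 3000
    kb_mean_degree: int = 6
    kb_n_planted_hubs: int = 2
    frac_nonmouse_mirna: float = 0.10
    frac_precursor_mirna: float = 0.10
    frac_duplicate_genes: float = 0.05

    def validate(self) -> None:
        if self.n_de_mirna_per_time > self.n_mirna_probes:
            raise ValueError("n_de_mirna_per_time exceeds n_mirna_probes")
        for lo, hi in (self.mirna_fc_range, self.mrna_fc_range):
            if abs(lo) < 1 or abs(hi) < 1:
                raise ValueError("fold-change magnitudes must be >= 1 (signed-linear convention)")
        if self.kb_mean_degree >= self.kb_n_molecules:
            raise ValueError("kb_mean_degree must be < kb_n_molecules")
        for t, targets in self.lag_model.items():
            if any(tt < t for tt in targets):
                raise ValueError("lag model must not place target changes before the miRNA change")
        if not 0 <= self.same_sign_fraction <= 1:
            raise ValueError("same_sign_fraction must lie in [0, 1]")
        if not 0 <= self.decoy_interaction_fraction:
            raise ValueError("decoy_interaction_fraction must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lag_model"] = {str(k): list(v) for k, v in self.lag_model.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "lag_model" in d:
            d["lag_model"] = {int(k): tuple(v) for k, v in d["lag_model"].items()}
        for key in ("regions", "times_h", "mirna_fc_range", "mrna_fc_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def detection_p_from_values(values: np.ndarray) -> np.ndarray:
    """Upper-tail probability of each intensity under the background model."""
    return stats.norm.sf(values, loc=BACKGROUND_MEAN, scale=BACKGROUND_SD)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for region in config.regions:
        for t in config.times_h:
            for cond, tag in ((TREATED, "cie"), (CONTROL, "air")):
                for i in range(config.n_per_group):
                    rows.append(
                        {
                            "sample_id": f"{region}_{t}h_{tag}_{i + 1:02d}",
                            "region": region,
                            "time_h": t,
                            "condition": cond,
                            "animal_id": f"A{t}_{tag}_{i + 1:02d}",
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _mirna_probe_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_mirna_probes
    ids = [f"miRprobe{i + 1:04d}" for i in range(n)]
    species = np.where(rng.random(n) < config.frac_nonmouse_mirna, "rat", "mouse")
    maturity = np.where(rng.random(n) < config.frac_precursor_mirna, "precursor", "mature")
    annotation = [f"mmu-miR-{i + 1:04d}" if sp == "mouse" else f"rno-miR-{i + 1:04d}" for i, sp in enumerate(species)]
    return pd.DataFrame(
        {"species": species, "maturity": maturity, "annotation": annotation},
        index=pd.Index(ids, name="probe_id"),
    )


def _mrna_probe_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_mrna_probes
    n_dup = int(round(config.frac_duplicate_genes * n))
    n_genes = n - n_dup
    genes = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    dup_genes = list(rng.choice(n_genes, size=n_dup, replace=False))
    annotation = genes + [genes[j] for j in dup_genes]
    ids = [f"mRNAprobe{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(
        {"species": ["mouse"] * n, "maturity": ["mature"] * n, "annotation": annotation},
        index=pd.Index(ids, name="probe_id"),
    )


def _apply_outliers(
    values: pd.DataFrame, sample_ids: Sequence[str], rng: np.random.Generator
) -> None:
    # An outlier array's intensities are decorrelated from the probe
    # baselines by permuting the column across probes: the marginal
    # intensity distribution is preserved but inter-array correlation is
    # destroyed, which is what array-QC outlier screens respond to.
    for sid in sample_ids:
        col = values[sid].to_numpy()
        values[sid] = col[rng.permutation(len(col))]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate the paired miRNA and mRNA expression datasets.

    Returns the miRNA dataset, the mRNA dataset (same animals), and the
    :class:`GroundTruth` record of every planted effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    samples = _sample_table(config)
    mirna_probes = _mirna_probe_table(config, rng)
    mrna_probes = _mrna_probe_table(config, rng)

    mirna_mu = rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_mirna_probes)
    mrna_mu = rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_mrna_probes)

    eligible_mirna = [
        i
        for i in range(config.n_mirna_probes)
        if mirna_probes["species"].iloc[i] == "mouse"
        and mirna_probes["maturity"].iloc[i] == "mature"
        and mirna_mu[i] >= PLANT_MIN_BASELINE
    ]
    gene_first_probe: dict[str, int] = {}
    for i, g in enumerate(mrna_probes["annotation"]):
        gene_first_probe.setdefault(g, i)
    eligible_genes = [g for g, i in gene_first_probe.items() if mrna_mu[i] >= PLANT_MIN_BASELINE]

    need = len(config.regions) * len(config.times_h) * config.n_de_mirna_per_time
    if need > len(eligible_mirna):
        raise ValueError(
            f"not enough plantable miRNA probes ({len(eligible_mirna)}) for "
            f"{need} requested DE miRNAs; increase n_mirna_probes"
        )

    # per-(probe, region, time) and (gene, region, time) log2 shifts applied
    # to treated samples
    mirna_shift: dict[tuple[int, str, int], float] = {}
    gene_shift: dict[tuple[str, str, int], float] = {}
    target_map: dict[str, tuple[str, ...]] = {}

    pool = list(eligible_mirna)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    lo_m, hi_m = abs(config.mirna_fc_range[0]), abs(config.mirna_fc_range[1])
    lo_g, hi_g = abs(config.mrna_fc_range[0]), abs(config.mrna_fc_range[1])

    for region in config.regions:
        for t in config.times_h:
            for _ in range(config.n_de_mirna_per_time):
                i = next(pool_iter)
                probe = mirna_probes.index[i]
                name = mirna_probes["annotation"].iloc[i]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                mag = rng.uniform(lo_m, hi_m)
                fc = sign * mag
                mirna_shift[(i, region, t)] = sign * np.log2(mag)
                truth.de_mirnas.add((probe, region, t, round(fc, 6)))

                if name not in target_map:
                    target_map[name] = tuple(
                        str(g) for g in rng.choice(eligible_genes, size=config.n_targets_per_mirna, replace=False)
                    )
                for gene in target_map[name]:
                    for tt in config.lag_model.get(t, ()):
                        same_sign = rng.random() < config.same_sign_fraction
                        gsign = sign if same_sign else -sign
                        gmag = rng.uniform(lo_g, hi_g)
                        key = (gene, region, tt)
                        if key not in gene_shift:
                            gene_shift[key] = gsign * np.log2(gmag)
                            truth.de_targets.add((gene, region, tt, round(gsign * gmag, 6)))
                        truth.true_pairs.add((name, gene, t, tt))

    def build_matrix(
        mu: np.ndarray,
        probes: pd.DataFrame,
        shifts: dict,
        by_gene: bool,
    ) -> pd.DataFrame:
        vals = np.empty((len(mu), len(samples)))
        vals[:] = mu[:, None]
        vals += rng.normal(0.0, config.noise_sd, size=vals.shape) if config.noise_sd > 0 else 0.0
        values = pd.DataFrame(vals, index=probes.index, columns=samples.index)
        ann = probes["annotation"]
        for key, shift in shifts.items():
            ident, region, t = key
            cols = samples.index[
                (samples["region"] == region)
                & (samples["time_h"] == t)
                & (samples["condition"] == TREATED)
            ]
            if by_gene:
                rows = ann.index[ann == ident]
            else:
                rows = [probes.index[ident]]
            values.loc[rows, cols] += shift
        return values

    mirna_values = build_matrix(mirna_mu, mirna_probes, mirna_shift, by_gene=False)
    mrna_values = build_matrix(mrna_mu, mrna_probes, gene_shift, by_gene=True)

    if config.n_outlier_samples > 0:
        out = rng.choice(samples.index.to_numpy(), size=config.n_outlier_samples, replace=False)
        truth.outlier_samples = set(out)
        _apply_outliers(mirna_values, out, rng)

    ds_mirna = ExpressionDataset(
        values=mirna_values,
        detection_p=pd.DataFrame(
            detection_p_from_values(mirna_values.to_numpy()),
            index=mirna_values.index,
            columns=mirna_values.columns,
        ),
        samples=samples.copy(),
        probes=mirna_probes,
    )
    ds_mrna = ExpressionDataset(
        values=mrna_values,
        detection_p=pd.DataFrame(
            detection_p_from_values(mrna_values.to_numpy()),
            index=mrna_values.index,
            columns=mrna_values.columns,
        ),
        samples=samples.copy(),
        probes=mrna_probes,
    )
    return ds_mirna, ds_mrna, truth


# ----------------------------------------------------------------------
# Interaction table
# ----------------------------------------------------------------------

def simulate_interactions(
    config: SimulationConfig, truth: GroundTruth
) -> list[InteractionRecord]:
    """Build the miRNA->gene interaction table.

    Every planted regulation appears with evidence that passes the
    confidence filter.  Decoy records (``round(decoy_interaction_fraction
    * n_true)`` of them) are added between random miRNA/gene identifiers;
    half of the decoys deliberately fail the confidence filter
    (predicted_low evidence, a non-conserved miRNA, or a weak context
    score with no conserved site).
    """
    rng = np.random.default_rng(config.seed + 1)
    true_mg = sorted({(m, g) for (m, g, _t1, _t2) in truth.true_pairs})
    records: list[InteractionRecord] = []
    for m, g in true_mg:
        if rng.random() < 0.4:
            records.append(InteractionRecord(m, g, "experimental", bool(rng.random() < 0.8), int(rng.integers(0, 3)), float(rng.uniform(-0.6, 0.0))))
        else:
            if rng.random() < 0.5:
                # conserved site route
                records.append(InteractionRecord(m, g, "predicted_high", True, int(rng.integers(1, 4)), float(rng.uniform(-0.5, 0.0))))
            else:
                # strong context-score route
                records.append(InteractionRecord(m, g, "predicted_high", True, 0, float(rng.uniform(-0.9, -0.4))))

    n_decoys = int(round(config.decoy_interaction_fraction * len(true_mg)))
    mirna_names = sorted({m for m, _ in true_mg}) or ["mmu-miR-0001"]
    gene_pool = sorted({g for (g, _r, _t, _f) in truth.de_targets} | {f"Gene{i + 1:04d}" for i in range(200)})
    seen = set(true_mg)
    made = 0
    while made < n_decoys:
        m = f"mmu-miR-d{rng.integers(0, 10_000):04d}" if rng.random() < 0.5 else str(rng.choice(mirna_names))
        g = str(rng.choice(gene_pool))
        if (m, g) in seen:
            continue
        seen.add((m, g))
        if made % 2 == 0:
            # confidence-passing decoy
            records.append(InteractionRecord(m, g, "predicted_high", True, int(rng.integers(1, 3)), float(rng.uniform(-0.6, 0.0))))
        else:
            mode = made // 2 % 3
            if mode == 0:
                records.append(InteractionRecord(m, g, "predicted_low", True, int(rng.integers(0, 2)), float(rng.uniform(-0.9, 0.0))))
            elif mode == 1:
                records.append(InteractionRecord(m, g, "predicted_high", False, int(rng.integers(0, 2)), -0.9))
            else:
                records.append(InteractionRecord(m, g, "predicted_high", True, 0, -0.3))
        made += 1
    return records


# ----------------------------------------------------------------------
# Knowledgebase graph and cell-type lists
# ----------------------------------------------------------------------

def simulate_knowledgebase(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[nx.Graph, dict[str, list[str]]]:
    """Molecule-interaction graph plus named cell-type gene sets.

    The graph is simple and undirected with a heavy-tailed
    (preferential-attachment) degree sequence over all simulated genes
    and miRNAs plus filler molecules.  Each planted hub is wired to at
    least 20 dataset (planted-DE) molecules and recorded in the truth.
    The "neuron" cell-type list carries the planted enrichment: it is
    seeded with planted 120h target genes.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_genes = config.n_mrna_probes - int(round(config.frac_duplicate_genes * config.n_mrna_probes))
    genes = sorted({g for (g, _r, _t, _f) in truth.de_targets} | {f"Gene{i + 1:04d}" for i in range(n_genes)})
    # de_mirnas holds probe ids; networks operate on annotation-level
    # names, which are the true_pairs' first members.
    mirnas = sorted({m for (m, _g, _t1, _t2) in truth.true_pairs})
    n_named = len(genes) + len(mirnas)
    n_filler = max(0, config.kb_n_molecules - n_named)
    molecules = genes + mirnas + [f"KBmol{i + 1:05d}" for i in range(n_filler)]
    n = len(molecules)

    m_attach = max(1, int(round(config.kb_mean_degree / 2)))
    g_int = nx.barabasi_albert_graph(n, m_attach, seed=int(rng.integers(0, 2**31 - 1)))
    order = rng.permutation(n)
    mapping = {i: molecules[order[i]] for i in range(n)}
    g = nx.relabel_nodes(g_int, mapping)

    for mol in molecules:
        if mol.startswith("KBmol"):
            typ = "other"
        elif mol in set(mirnas):
            typ = "mirna"
        else:
            typ = "gene"
        g.nodes[mol]["type"] = typ
        g.nodes[mol]["family_id"] = ""

    # gene families: pairs/triples of genes sharing a family id
    fam_genes = [str(g) for g in rng.choice(genes, size=min(60, len(genes) // 10), replace=False)]
    fi = 0
    while fam_genes:
        size = int(rng.integers(2, 4))
        members, fam_genes = fam_genes[:size], fam_genes[size:]
        fi += 1
        for mol in members:
            if mol in g:
                g.nodes[mol]["family_id"] = f"FAM{fi:03d}"

    # planted hubs: connector molecules wired to >= 20 planted-DE
    # molecules, concentrated within each region's late-time datasets so
    # the hub shows up in networks derived from several paired datasets
    fillers = [m for m in molecules if m.startswith("KBmol")]
    mirna_by_region: dict[str, list[str]] = {r: [] for r in config.regions}
    # map planted miRNA probes to names via true_pairs' regulators; the
    # regional grouping follows de_targets, which carries the region
    t_late = max(config.times_h, default=0)
    de_late = {r: {g_ for (g_, rr, t, _f) in truth.de_targets if rr == r and t == t_late} for r in config.regions}
    regulated_at = {
        t_mir: {g_ for (_m, g_, t1, t2) in truth.true_pairs if t1 == t_mir and t2 == t_late}
        for t_mir in config.times_h
    }
    hub_ids = [f"KBhub{i + 1:02d}" for i in range(config.kb_n_planted_hubs)]
    for hid in hub_ids:
        g.add_node(hid, type="other", family_id="")
        wired: set[str] = set()
        for region in config.regions:
            for t_mir in config.times_h:
                pool = sorted(regulated_at[t_mir] & de_late[region])
                take = int(np.ceil(0.6 * len(pool)))
                if take:
                    wired |= {str(m) for m in rng.choice(pool, size=take, replace=False)}
        n_more = max(0, 20 - len(wired))
        if n_more:
            extra_pool = sorted({g_ for (g_, _r, _t, _f) in truth.de_targets} - wired) + mirnas
            wired |= {str(m) for m in rng.choice(extra_pool, size=min(n_more, len(extra_pool)), replace=False)}
        for mol in wired:
            g.add_edge(hid, mol)
        # a few filler contacts so hubs sit inside the global graph
        for mol in rng.choice(fillers, size=min(5, len(fillers)), replace=False):
            g.add_edge(hid, str(mol))
        truth.planted_hubs.add(hid)

    g.remove_edges_from(nx.selfloop_edges(g))

    targets_120 = sorted({g_ for (g_, _r, t, _f) in truth.de_targets if t == 120})
    non_planted = [g_ for g_ in genes if g_ not in set(targets_120)]
    cell_lists: dict[str, list[str]] = {}
    n_seed = max(1, int(0.4 * len(targets_120)))
    seeded = [str(g) for g in rng.choice(targets_120, size=n_seed, replace=False)] if targets_120 else []
    filler_genes = [str(g) for g in rng.choice(non_planted, size=min(100, len(non_planted)), replace=False)]
    cell_lists["neuron"] = sorted(set(seeded + filler_genes[: 100 - len(seeded)]))
    for name in ("astrocyte", "microglia", "oligodendrocyte", "immune"):
        cell_lists[name] = sorted(str(g) for g in rng.choice(non_planted, size=min(100, len(non_planted)), replace=False))
    return g, cell_lists


# ----------------------------------------------------------------------
# Temporal-profile generator for the clustering stage
# ----------------------------------------------------------------------

def simulate_temporal_profiles(
    n_patterns: int,
    n_per_pattern: int = 10,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Three-point temporal log-ratio profiles from planted patterns.

    After centering and scaling, three-point profiles live on a circle;
    the planted prototypes are placed at equally spaced angles on that
    circle, so ``n_patterns`` well-separated temporal shapes exist for
    any reasonable ``n_patterns``.  Raw profiles are random affine
    transforms of the prototype plus Gaussian noise.

    Returns a profiles DataFrame (rows = miRNA ids, columns 0/8/120 h)
    and the integer pattern labels.
    """
    rng = np.random.default_rng(seed)
    u1 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
    u2 = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
    angles = 2 * np.pi * np.arange(n_patterns) / n_patterns
    protos = np.outer(np.cos(angles), u1) + np.outer(np.sin(angles), u2)

    rows, labels = [], []
    for j in range(n_patterns):
        for _ in range(n_per_pattern):
            amp = rng.uniform(0.5, 2.0)
            offset = rng.uniform(-1.0, 1.0)
            rows.append(amp * protos[j] + offset + rng.normal(0, noise_sd, 3))
            labels.append(j)
    ids = [f"mmu-miR-s{i + 1:03d}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=ids, columns=[0, 8, 120])
    return df, np.asarray(labels)
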