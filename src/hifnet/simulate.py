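"""Two-cohort synthetic expression data with planted, recoverable structure.

The generator emulates the data regime the pipeline was designed for:

* two AML-like cohorts measured on nested platforms — cohort A's probes are a
  subset of cohort B's (``shared_probe_fraction`` of B's probes are shared),
  so the cross-platform intersection is cohort A's probe set;
* seed-anchored star modules: each seed anchor gene drives its member genes
  linearly (``member = beta * anchor + noise``), giving every anchor-member
  pair a planted edge and every member-member pair of a star an *indirect*
  dependency that exercises data-processing-inequality pruning;
* an APL-specific structure: a small up-regulated module and a larger
  down-regulated module, each a group of seed anchors plus members, whose
  genes are mean-shifted by +/- ``apl_shift`` in the M3 samples of both
  cohorts;
* FAB subtype labels M0..M5 with cohort-specific sample counts;
* multi-probe genes (1-3 probes per gene, probe = gene value + probe noise);
* "dead" probes — near-constant values with rare spikes — the intended
  victims of the entropy filter (real arrays carry unexpressed probe sets;
  without them the filter would cull informative probes at random);
* regulator miRNAs up-shifted in M3 and negatively loaded on the
  down-module's genes, among decoy miRNAs;
* a treatment time-course in which the APL shifts relax exponentially toward
  baseline.

Everything is deterministic under (config, seed); changing only the seed
changes values but neither dimensions nor truth-structure sizes (the number
of probes per gene cycles deterministically through its configured range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import Subnetwork
from .datatypes import ExpressionMatrix, MiRNAMatrix, ProbeAnnotation, SeedList

__all__ = [
    "GeneratorConfig",
    "TruthModel",
    "generate_cohorts",
    "generate_mirnas",
    "generate_timecourse",
    "generate_promyelocyte_cohort",
    "evaluate_recovery",
    "RecoveryReport",
    "mirna_hit_rate",
]


def _default_samples_a():
    return {"M0": 15, "M1": 30, "M2": 30, "M3": 20, "M4": 30, "M5": 25}


def _default_samples_b():
    return {"M0": 12, "M1": 28, "M2": 30, "M3": 20, "M4": 30, "M5": 25}


@dataclass
class GeneratorConfig:
    """Knobs of the planted-structure generator (defaults are desk-scale:
    ~2,000 probes, ~150 samples per cohort, 100 seed anchors)."""

    n_seed_anchors: int = 100
    members_per_anchor: int = 5
    n_background_genes: int = 250
    n_dead_genes: int = 200
    probes_per_gene: tuple[int, int] = (1, 3)
    samples_a: dict = field(default_factory=_default_samples_a)
    samples_b: dict = field(default_factory=_default_samples_b)
    case_label: str = "M3"
    beta: float = 1.0
    sigma_gene: float = 0.3
    sigma_probe: float = 0.3
    apl_up_size: int = 30
    apl_up_anchors: int = 2
    apl_down_size: int = 60
    apl_down_anchors: int = 4
    apl_shift: float = 1.5
    n_regulator_mirnas: int = 3
    n_decoy_mirnas: int = 20
    targets_per_regulator: int = 20
    mirna_loading: float = -0.8
    mirna_shift: float = 1.5
    shared_probe_fraction: float = 0.9
    dead_base_sd: float = 0.05
    dead_spike_sd: float = 3.0
    dead_spike_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        counts = [
            self.n_seed_anchors, self.members_per_anchor, self.n_background_genes,
            self.apl_up_size, self.apl_down_size, self.apl_up_anchors,
            self.apl_down_anchors,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all structural counts must be positive")
        if not 0 < self.shared_probe_fraction <= 1:
            raise ValueError("shared_probe_fraction must be in (0, 1]")
        if self.apl_shift < 0:
            raise ValueError("apl_shift must be >= 0")
        if self.apl_up_anchors + self.apl_down_anchors > self.n_seed_anchors:
            raise ValueError("more APL anchors than seed anchors")
        if self.apl_up_size <= self.apl_up_anchors or self.apl_down_size <= self.apl_down_anchors:
            raise ValueError("APL module must be larger than its anchor count")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("invalid probes_per_gene range")
        if self.n_regulator_mirnas * self.targets_per_regulator > self.apl_down_size:
            raise ValueError("regulator targets exceed the down-module size")
        if self.case_label not in self.samples_a or self.case_label not in self.samples_b:
            raise ValueError("case_label missing from cohort sample counts")


@dataclass
class TruthModel:
    """Planted structure emitted alongside the data, for recovery scoring."""

    planted_edges: list[tuple[str, str]]          # (anchor gene, member gene)
    indirect_pairs: list[tuple[str, str]]         # member-member via shared anchor
    modules: dict[str, set]                       # apl_up / apl_down / background / dead / seed
    member_of: dict[str, str]                     # member gene -> its anchor
    subtype_shifts: dict[str, float]              # gene -> shift applied in case samples
    regulators: dict[str, list[str]]              # miRNA id -> target gene list
    seed: int = 0

    @property
    def apl_genes(self) -> set:
        return self.modules["apl_up"] | self.modules["apl_down"]


# ---------------------------------------------------------------------------
# structure (seed-independent except through config.seed streams)
# ---------------------------------------------------------------------------

def _build_structure(cfg: GeneratorConfig):
    """Deterministic gene/probe layout and planted wiring."""
    anchors = [f"SEED{i:03d}" for i in range(cfg.n_seed_anchors)]
    up_anchors = anchors[: cfg.apl_up_anchors]
    down_anchors = anchors[cfg.apl_up_anchors: cfg.apl_up_anchors + cfg.apl_down_anchors]
    regular_anchors = anchors[cfg.apl_up_anchors + cfg.apl_down_anchors:]

    member_of: dict[str, str] = {}
    up_members = [f"UPM{i:03d}" for i in range(cfg.apl_up_size - cfg.apl_up_anchors)]
    for i, g in enumerate(up_members):
        member_of[g] = up_anchors[i % len(up_anchors)]
    down_members = [f"DNM{i:03d}" for i in range(cfg.apl_down_size - cfg.apl_down_anchors)]
    for i, g in enumerate(down_members):
        member_of[g] = down_anchors[i % len(down_anchors)]
    reg_members = []
    for ai, anchor in enumerate(regular_anchors):
        for k in range(cfg.members_per_anchor):
            g = f"TG{ai:03d}_{k}"
            member_of[g] = anchor
            reg_members.append(g)

    background = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    dead = [f"DEAD{i:04d}" for i in range(cfg.n_dead_genes)]

    genes = anchors + up_members + down_members + reg_members + background + dead

    # probes per gene cycle deterministically through the configured range so
    # that dimensions do not depend on the rng seed
    lo, hi = cfg.probes_per_gene
    span = hi - lo + 1
    probes: list[str] = []
    probe_gene: dict[str, str] = {}
    gene_probes: dict[str, list[str]] = {}
    for gi, g in enumerate(genes):
        k = lo + (gi % span)
        plist = [f"{g}_p{j + 1}" for j in range(k)]
        probes.extend(plist)
        gene_probes[g] = plist
        for p in plist:
            probe_gene[p] = g

    # cohort-B-only decoy genes sized so that the shared probes are the
    # configured fraction of B's probe list (platform nesting: A subset of B)
    n_shared = len(probes)
    n_extra = int(round(n_shared * (1.0 - cfg.shared_probe_fraction)
                        / cfg.shared_probe_fraction))
    b_only_genes: list[str] = []
    b_only_probes: list[str] = []
    gi = 0
    while len(b_only_probes) < n_extra:
        g = f"BX{gi:04d}"
        k = lo + (gi % span)
        plist = [f"{g}_p{j + 1}" for j in range(k)][: n_extra - len(b_only_probes)]
        b_only_genes.append(g)
        gene_probes[g] = plist
        for p in plist:
            probe_gene[p] = g
        b_only_probes.extend(plist)
        gi += 1

    modules = {
        "seed": set(anchors),
        "apl_up": set(up_anchors) | set(up_members),
        "apl_down": set(down_anchors) | set(down_members),
        "background": set(background) | set(b_only_genes),
        "dead": set(dead),
    }
    shifts = {g: cfg.apl_shift for g in modules["apl_up"]}
    shifts.update({g: -cfg.apl_shift for g in modules["apl_down"]})

    planted = [(a, m) for m, a in member_of.items()]
    by_anchor: dict[str, list[str]] = {}
    for m, a in member_of.items():
        by_anchor.setdefault(a, []).append(m)
    indirect = []
    for a, ms in by_anchor.items():
        ms = sorted(ms)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                indirect.append((ms[i], ms[j]))

    # regulator miRNAs target disjoint chunks of the down module
    down_genes = sorted(modules["apl_down"])
    regulators = {}
    for r in range(cfg.n_regulator_mirnas):
        targets = down_genes[r * cfg.targets_per_regulator:(r + 1) * cfg.targets_per_regulator]
        regulators[f"mir-reg-{r + 1:02d}"] = targets

    return {
        "genes": genes,
        "anchors": anchors,
        "member_of": member_of,
        "shared_probes": probes,
        "b_only_probes": b_only_probes,
        "probe_gene": probe_gene,
        "gene_probes": gene_probes,
        "modules": modules,
        "shifts": shifts,
        "planted": planted,
        "indirect": indirect,
        "regulators": regulators,
    }


def _sample_ids(prefix: str, counts: dict) -> tuple[list[str], pd.Series]:
    ids, labels = [], {}
    for label, n in counts.items():
        for i in range(n):
            sid = f"{prefix}_{label}_{i:03d}"
            ids.append(sid)
            labels[sid] = label
    return ids, pd.Series(labels, dtype=object)


def _cohort_values(cfg: GeneratorConfig, struct, probe_list, counts, rng, prefix):
    sample_ids, labels = _sample_ids(prefix, counts)
    n = len(sample_ids)
    case = np.array([labels[s] == cfg.case_label for s in sample_ids])

    gene_vals: dict[str, np.ndarray] = {}
    for a in struct["anchors"]:
        gene_vals[a] = rng.standard_normal(n)
    for m in sorted(struct["member_of"]):
        a = struct["member_of"][m]
        gene_vals[m] = cfg.beta * gene_vals[a] + cfg.sigma_gene * rng.standard_normal(n)
    for g in struct["genes"]:
        if g in gene_vals:
            continue
        if g in struct["modules"]["dead"]:
            v = cfg.dead_base_sd * rng.standard_normal(n)
            spikes = rng.random(n) < cfg.dead_spike_rate
            v[spikes] = cfg.dead_spike_sd * rng.standard_normal(int(spikes.sum()))
            gene_vals[g] = v
        else:
            gene_vals[g] = rng.standard_normal(n)
    for g in sorted(set(struct["probe_gene"][p] for p in probe_list) - set(gene_vals)):
        gene_vals[g] = rng.standard_normal(n)  # cohort-only decoy genes

    for g, shift in struct["shifts"].items():
        gene_vals[g] = gene_vals[g] + shift * case

    rows = np.empty((len(probe_list), n))
    for i, p in enumerate(probe_list):
        rows[i] = gene_vals[struct["probe_gene"][p]] + cfg.sigma_probe * rng.standard_normal(n)
    values = pd.DataFrame(rows, index=probe_list, columns=sample_ids)
    return ExpressionMatrix(values, labels, name=prefix)


def generate_cohorts(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ProbeAnnotation, SeedList, TruthModel]:
    """Draw the two cohorts plus annotation, seed list, and truth model.

    The same (config, seed) always yields bit-identical outputs; cohort B is
    drawn independently from the same planted truth with its own sample
    counts and its extra platform-specific probes.
    """
    struct = _build_structure(cfg)
    rng_a = np.random.default_rng([cfg.seed, 1])
    rng_b = np.random.default_rng([cfg.seed, 2])
    em_a = _cohort_values(cfg, struct, struct["shared_probes"], cfg.samples_a, rng_a, "A")
    em_b = _cohort_values(
        cfg, struct, struct["shared_probes"] + struct["b_only_probes"],
        cfg.samples_b, rng_b, "B",
    )
    annotation = ProbeAnnotation(struct["probe_gene"])
    seeds = SeedList(genes=list(struct["anchors"]))
    truth = TruthModel(
        planted_edges=struct["planted"],
        indirect_pairs=struct["indirect"],
        modules=struct["modules"],
        member_of=struct["member_of"],
        subtype_shifts=struct["shifts"],
        regulators=struct["regulators"],
        seed=cfg.seed,
    )
    return em_a, em_b, annotation, seeds, truth


def generate_mirnas(
    cfg: GeneratorConfig,
    truth: TruthModel,
    cohort: ExpressionMatrix,
) -> MiRNAMatrix:
    """Draw the miRNA matrix for a cohort and couple it to the mRNA data.

    Regulator miRNAs are mean-shifted upward in the case samples; decoys are
    independent noise.  For each regulator, the loading term
    ``mirna_loading * miRNA`` is **added in place to the probe rows of its
    target genes in the passed cohort**, establishing the planted
    anti-correlation.  Deterministic under the config seed and cohort name.
    """
    stream = {"A": 11, "B": 12}.get(cohort.name or "B", 13)
    rng = np.random.default_rng([cfg.seed, stream])
    labels = cohort.require_labels()
    case = (labels == cfg.case_label).to_numpy()
    n = cohort.n_samples

    rows, ids = [], []
    probe_index = cohort.values.index
    for mirna_id in sorted(truth.regulators):
        v = rng.standard_normal(n) + cfg.mirna_shift * case
        ids.append(mirna_id)
        rows.append(v)
        for gene in truth.regulators[mirna_id]:
            for probe in probe_index[probe_index.str.startswith(f"{gene}_p")]:
                cohort.values.loc[probe] = (
                    cohort.values.loc[probe].to_numpy() + cfg.mirna_loading * v
                )
    for d in range(cfg.n_decoy_mirnas):
        ids.append(f"mir-dec-{d + 1:02d}")
        rows.append(rng.standard_normal(n))
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=cohort.sample_ids)
    return MiRNAMatrix(values, cohort.labels, name=f"{cohort.name}_mirna")


def generate_timecourse(
    cfg: GeneratorConfig,
    truth: TruthModel,
    timepoints=(0.0, 6.0, 12.0, 24.0, 48.0, 72.0),
    tau: float = 12.0,
    noise_sd: float = 0.05,
    n_background: int = 40,
) -> pd.DataFrame:
    """Treatment time-course in which the case shifts decay toward baseline.

    Each APL-module gene's expected value relaxes from its shifted mean as
    ``shift * exp(-t / tau)``; the reported value is the log2 fold change
    versus t = 0, i.e. ``shift * (exp(-t / tau) - 1)`` plus noise (exactly 0
    in the first column).  Background genes fluctuate around 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    timepoints = [float(t) for t in timepoints]
    if timepoints[0] != 0.0 or any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must start at 0 and be strictly increasing")
    rng = np.random.default_rng([cfg.seed, 21])
    genes = sorted(truth.apl_genes) + sorted(truth.modules["background"])[:n_background]
    shifts = np.array([truth.subtype_shifts.get(g, 0.0) for g in genes])
    t = np.array(timepoints)
    fc = shifts[:, None] * (np.exp(-t[None, :] / tau) - 1.0)
    noise = noise_sd * rng.standard_normal(fc.shape)
    noise[:, 0] = 0.0
    out = pd.DataFrame(fc + noise, index=pd.Index(genes, name="gene"), columns=t)
    return out


def generate_promyelocyte_cohort(
    cfg: GeneratorConfig,
    truth: TruthModel,
    annotation: ProbeAnnotation,
    n_pm: int = 5,
    n_apl: int = 14,
    profile_sd: float = 1.5,
) -> ExpressionMatrix:
    """Small normal-vs-leukemic promyelocyte cohort over the APL-module probes.

    Both groups carry distinct mean profiles: APL samples the planted case
    shifts, normal promyelocytes an independent per-gene profile of
    comparable magnitude; per-sample noise matches the cohort noise level.
    """
    rng = np.random.default_rng([cfg.seed, 31])
    genes = sorted(truth.apl_genes)
    probes = [p for g in genes for p in annotation.probes_of(g)]
    shifts = np.array([truth.subtype_shifts[annotation.gene_of(p)] for p in probes])
    pm_profile = profile_sd * rng.standard_normal(len(probes))
    n = n_pm + n_apl
    noise = rng.standard_normal((len(probes), n)) * np.sqrt(1 + cfg.sigma_probe**2)
    means = np.concatenate(
        [np.tile(pm_profile[:, None], (1, n_pm)), np.tile(shifts[:, None], (1, n_apl))],
        axis=1,
    )
    ids = [f"PM_{i:02d}" for i in range(n_pm)] + [f"APL_{i:02d}" for i in range(n_apl)]
    labels = pd.Series({s: ("PM" if s.startswith("PM") else "APL") for s in ids})
    return ExpressionMatrix(
        pd.DataFrame(means + noise, index=probes, columns=ids), labels, name="PM_vs_APL"
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    edge_precision: float
    edge_recall: float
    n_planted: int
    n_inferred_gene_pairs: int
    n_true_positive: int
    n_indirect_recovered: int
    module_jaccard: dict | None = None
    apl_gene_recovery: float | None = None
    background_gene_fraction: float | None = None


def _gene_pairs(graph: nx.Graph, annotation: ProbeAnnotation) -> set[frozenset]:
    pairs = set()
    for u, v in graph.edges:
        gu, gv = annotation.gene_of(u), annotation.gene_of(v)
        if gu != gv:  # same-gene probe pairs are trivial self-associations
            pairs.add(frozenset((gu, gv)))
    return pairs


def evaluate_recovery(
    inferred,
    truth: TruthModel,
    annotation: ProbeAnnotation,
    count_indirect_as_fp: bool = True,
) -> RecoveryReport:
    """Score an inferred network or subnetwork against the planted truth.

    Probe-pair edges are mapped to gene pairs (same-gene pairs dropped).
    Precision counts recovered member-member pairs of a star as false
    positives unless ``count_indirect_as_fp`` is False, in which case they are
    excluded from the denominator and only reported.  For a
    :class:`Subnetwork`, module recovery (per-direction Jaccard against the
    planted APL modules, overall APL gene recovery, and the background-gene
    contamination fraction) is reported as well.
    """
    if not truth.planted_edges:
        raise ValueError("truth model has no planted edges")
    graph = inferred.graph if isinstance(inferred, Subnetwork) else inferred
    inferred_pairs = _gene_pairs(graph, annotation)
    planted = {frozenset(e) for e in truth.planted_edges}
    indirect = {frozenset(e) for e in truth.indirect_pairs}
    tp = inferred_pairs & planted
    indirect_found = inferred_pairs & indirect
    denom_pairs = inferred_pairs if count_indirect_as_fp else inferred_pairs - indirect
    precision = len(tp) / len(denom_pairs) if denom_pairs else 0.0
    recall = len(tp) / len(planted)

    report = RecoveryReport(
        edge_precision=precision,
        edge_recall=recall,
        n_planted=len(planted),
        n_inferred_gene_pairs=len(inferred_pairs),
        n_true_positive=len(tp),
        n_indirect_recovered=len(indirect_found),
    )
    if isinstance(inferred, Subnetwork):
        gene_dirs = inferred.gene_directions()
        up = {g for g, d in gene_dirs.items() if d == "up"}
        down = {g for g, d in gene_dirs.items() if d == "down"}
        all_genes = set(gene_dirs.index)
        tu, td = truth.modules["apl_up"], truth.modules["apl_down"]
        report.module_jaccard = {
            "apl_up": len(up & tu) / len(up | tu) if up | tu else 1.0,
            "apl_down": len(down & td) / len(down | td) if down | td else 1.0,
        }
        report.apl_gene_recovery = len(all_genes & truth.apl_genes) / len(truth.apl_genes)
        report.background_gene_fraction = (
            len(all_genes & truth.modules["background"]) / len(all_genes)
            if all_genes else 0.0
        )
    return report


def mirna_hit_rate(ranking: list[str], truth: TruthModel, k: int | None = None) -> float:
    """Fraction of planted regulator miRNAs found in the ranking's top k."""
    regs = set(truth.regulators)
    if not regs:
        raise ValueError("truth model has no regulator miRNAs")
    if k is None:
        k = len(regs)
    top = set(ranking[:k])
    return len(top & regs) / min(k, len(regs))
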