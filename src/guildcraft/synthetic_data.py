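"""Synthetic study generator with known ground truth.

Emulates the data structure of a four-arm mouse feeding study (NFD/HFD diet
x ad libitum/TRF regime): an ASV-level count table with planted co-abundance
blocks (guilds), repeated sampling of the same mice at baseline and after
intervention, SILVA-style taxonomy with a fixed fraction of ASVs
unclassifiable at genus level, a 6-hourly two-day time course with
rhythmic blocks, and metabolic phenotypes linked to named blocks.

Model: each feature belongs to one block; its log abundance in a sample is

    eta = mu_f + sigma * (sqrt(rho) z_block + sqrt(1-rho) eps) + subject
          + group effect (+ amplitude * cos(2 pi (zt - phase)/24))

with z_block a per-sample latent factor shared by the block's members, so
the pairwise within-block log-scale correlation is ~rho.  Compositions are
softmax(eta) with per-cell dropout calibrated to the target sparsity, and
counts are multinomial at the library depth, so per-sample totals equal the
depth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .taxon_aggregation import TaxonomyMap

DIETS = ("NFD", "HFD")
REGIMES = ("ad_libitum", "TRF")
GROUPS = tuple(f"{d}_{r}" for d in DIETS for r in REGIMES)


def _default_block_effects() -> dict:
    # seven TRF-responding blocks in the HFD arm, mixed directions
    return {
        "HFD_TRF": {"B1": 1.0, "B2": 1.0, "B3": 1.0, "B4": -1.0,
                    "B5": -1.0, "B6": 0.8, "B7": -0.8},
    }


def _default_phenotypes() -> dict:
    # five of the seven responding blocks carry phenotype links
    return {
        "fasting_glucose": {
            "intercept": 8.0,
            "beta": {"B1": -60.0, "B2": -60.0},
            "noise_sd": 0.5,
        },
        "auc_ogtt": {
            "intercept": 1500.0,
            "beta": {"B3": -9000.0, "B4": 9000.0, "B5": 9000.0},
            "noise_sd": 90.0,
        },
    }


def _default_rhythmic_blocks() -> dict:
    return {"B1": (1.5, 14.0), "B2": (1.5, 2.0)}  # block -> (amplitude, phase ZT h)


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study's scales
    (4 diet x regime groups, 15 mice each, two sampling timepoints, ~1100
    ASVs at ~80% sparsity, library depth 18 000)."""

    n_subjects: int = 60
    samples_per_subject: int = 2
    n_features: int = 1100
    n_blocks: int = 34
    within_block_corr: float = 0.7
    latent_sd: float = 1.0
    subject_sd: float = 0.5
    base_abundance_sd: float = 2.0
    block_effects: dict = field(default_factory=_default_block_effects)
    unclassifiable_fraction: float = 0.4
    sparsity_target: float = 0.80
    depth: int = 18_000
    rhythmic_blocks: dict = field(default_factory=_default_rhythmic_blocks)
    timecourse_replicates: int = 4
    timecourse_hours: float = 48.0
    timecourse_interval: float = 6.0
    timecourse_group: str = "HFD_TRF"
    phenotypes: dict = field(default_factory=_default_phenotypes)
    seed: int = 0

    def __post_init__(self):
        for name, value in (
            ("within_block_corr", self.within_block_corr),
            ("unclassifiable_fraction", self.unclassifiable_fraction),
            ("sparsity_target", self.sparsity_target),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_blocks > self.n_features:
            raise ValueError("n_blocks cannot exceed n_features")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for amp_phase in self.rhythmic_blocks.values():
            if amp_phase[0] < 0:
                raise ValueError("rhythm amplitude must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth: block memberships, group effects, rhythmic
    phases, phenotype coefficients and the genus-unclassifiable set."""

    blocks: pd.Series  # feature -> block label
    block_effects: dict
    rhythmic_blocks: dict
    phenotypes: dict
    unclassifiable: list[str]

    def block_members(self, block: str) -> list[str]:
        return self.blocks.index[self.blocks == block].tolist()


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _feature_blocks(cfg: SimConfig) -> np.ndarray:
    """Round-robin assignment so blocks have near-equal sizes."""
    return np.array([f"B{(i % cfg.n_blocks) + 1}" for i in range(cfg.n_features)])


def _counts_from_eta(eta: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Softmax -> dropout calibrated to the sparsity target -> multinomial."""
    eta = eta - eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    # expected zero fraction from multinomial sampling alone
    s0 = float(np.mean((1.0 - p) ** cfg.depth))
    if s0 > cfg.sparsity_target + 0.05:
        raise ValueError(
            f"infeasible sparsity target {cfg.sparsity_target}: sampling alone "
            f"yields ~{s0:.2f} at depth {cfg.depth}"
        )
    delta = max(0.0, (cfg.sparsity_target - s0) / (1.0 - s0)) if s0 < 1 else 0.0
    if delta > 0:
        keep = rng.random(p.shape) >= delta
        # never blank an entire sample
        keep[np.arange(p.shape[0]), p.argmax(axis=1)] = True
        p = np.where(keep, p, 0.0)
        p /= p.sum(axis=1, keepdims=True)
    counts = np.empty(p.shape, dtype=np.int64)
    for i in range(p.shape[0]):
        counts[i] = rng.multinomial(cfg.depth, p[i])
    return counts


def _taxonomy(cfg: SimConfig, feature_ids, rng: np.random.Generator) -> tuple[TaxonomyMap, list[str]]:
    """SILVA-style lineages; a random unclassifiable_fraction of features get
    placeholder or truncated genus ranks."""
    n = len(feature_ids)
    n_unclass = int(round(cfg.unclassifiable_fraction * n))
    unclass_idx = set(rng.choice(n, size=n_unclass, replace=False).tolist())
    n_genera = max(1, (n - n_unclass) // 5 or 1)
    phyla = ("Firmicutes", "Bacteroidota", "Actinobacteriota", "Proteobacteria")

    def upper_ranks(key: int) -> list[str]:
        # lineage above genus is a function of the genus key, so members of
        # one genus share the full lineage (full-lineage genus identity)
        return [
            "d__Bacteria",
            f"p__{phyla[key % len(phyla)]}",
            f"c__Class{key % 8 + 1}",
            f"o__Order{key % 16 + 1}",
            f"f__Family{key % 40 + 1}",
        ]

    lineages = {}
    unclassifiable = []
    g = 0
    for i, fid in enumerate(feature_ids):
        if i in unclass_idx:
            base = upper_ranks(i)
            style = i % 3
            if style == 0:
                ranks = base  # truncated at family
            elif style == 1:
                ranks = base + ["g__"]
            else:
                ranks = base + ["g__uncultured"]
            unclassifiable.append(fid)
        else:
            genus = g % n_genera + 1
            ranks = upper_ranks(genus) + [f"g__Genus{genus}"]
            g += 1
        lineages[fid] = ranks
    return TaxonomyMap(lineages=lineages), unclassifiable


# ---------------------------------------------------------------------------
# cross-sectional community (baseline + post-intervention)
# ---------------------------------------------------------------------------

def simulate_community(cfg: SimConfig):
    """Generate (table, metadata, taxonomy, truth) for the two-timepoint
    repeated-sampling design.

    Subjects are split evenly over the four diet x regime groups; each
    contributes ``samples_per_subject`` samples (the first labeled
    ``baseline``, the last ``week12``).  Group log-fold effects apply to the
    post-intervention samples only, emulating a treatment response.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks = _feature_blocks(cfg)
    feature_ids = [f"ASV{i+1:04d}" for i in range(cfg.n_features)]
    block_of = {f: b for f, b in zip(feature_ids, blocks)}

    groups = [GROUPS[i % len(GROUPS)] for i in range(cfg.n_subjects)]
    subject_ids = [f"M{i+1:03d}" for i in range(cfg.n_subjects)]
    timepoints = ["baseline"] + ["week12"] * (cfg.samples_per_subject - 1)

    mu = rng.normal(0.0, cfg.base_abundance_sd, size=cfg.n_features)
    subj_fx = rng.normal(0.0, cfg.subject_sd, size=(cfg.n_subjects, cfg.n_features))
    rho = cfg.within_block_corr
    block_index = {b: np.flatnonzero(blocks == b) for b in np.unique(blocks)}

    rows, meta_rows, sample_ids = [], [], []
    s = 0
    for i, (subj, grp) in enumerate(zip(subject_ids, groups)):
        diet, regime = grp.split("_", 1)
        for t_idx in range(cfg.samples_per_subject):
            tp = timepoints[min(t_idx, len(timepoints) - 1)]
            z_block = rng.normal(size=cfg.n_blocks)
            eps = rng.normal(size=cfg.n_features)
            eta = mu + subj_fx[i].copy()
            for b, idx in block_index.items():
                bnum = int(b[1:]) - 1
                eta[idx] += cfg.latent_sd * (
                    np.sqrt(rho) * z_block[bnum] + np.sqrt(1 - rho) * eps[idx]
                )
            if tp != "baseline" and grp in cfg.block_effects:
                for b, shift in cfg.block_effects[grp].items():
                    if b not in block_index:
                        raise ValueError(f"unknown block {b!r} in block_effects")
                    eta[block_index[b]] += shift
            rows.append(eta)
            s += 1
            sample_ids.append(f"S{s:04d}")
            meta_rows.append(
                {
                    "sample-id": sample_ids[-1],
                    "subject-id": subj,
                    "cage": f"C{(i // 3) + 1:02d}",
                    "diet": diet,
                    "regime": regime,
                    "timepoint": tp,
                    "zt_hours": 1.0,
                }
            )

    counts = _counts_from_eta(np.array(rows), cfg, rng)
    table = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample-id"),
                         columns=feature_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample-id")
    tax, unclassifiable = _taxonomy(cfg, feature_ids, rng)
    truth = SimTruth(
        blocks=pd.Series(block_of, name="block"),
        block_effects=cfg.block_effects,
        rhythmic_blocks=cfg.rhythmic_blocks,
        phenotypes=cfg.phenotypes,
        unclassifiable=unclassifiable,
    )
    return table, meta, tax, truth


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

def simulate_timecourse(cfg: SimConfig):
    """Generate (table, metadata, truth) for one group's 6-hourly two-day
    fecal time course (``timecourse_replicates`` mice, each sampled at every
    timepoint).

    Rhythmic blocks gain ``amplitude * cos(2 pi (zt - phase) / 24)`` on the
    log scale, shared by all member features.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    blocks = _feature_blocks(cfg)
    feature_ids = [f"ASV{i+1:04d}" for i in range(cfg.n_features)]
    block_index = {b: np.flatnonzero(blocks == b) for b in np.unique(blocks)}
    for b, (amp, _) in cfg.rhythmic_blocks.items():
        if b not in block_index:
            raise ValueError(f"unknown rhythmic block {b!r}")
        if amp < 0:
            raise ValueError("rhythm amplitude must be non-negative")

    zts = np.arange(0.0, cfg.timecourse_hours, cfg.timecourse_interval)
    diet, regime = cfg.timecourse_group.split("_", 1)
    mu = rng.normal(0.0, cfg.base_abundance_sd, size=cfg.n_features)
    subj_fx = rng.normal(0.0, cfg.subject_sd,
                         size=(cfg.timecourse_replicates, cfg.n_features))
    rho = cfg.within_block_corr

    rows, meta_rows, sample_ids = [], [], []
    s = 0
    for zt in zts:
        for r in range(cfg.timecourse_replicates):
            z_block = rng.normal(size=cfg.n_blocks)
            eps = rng.normal(size=cfg.n_features)
            eta = mu + subj_fx[r].copy()
            for b, idx in block_index.items():
                bnum = int(b[1:]) - 1
                eta[idx] += cfg.latent_sd * (
                    np.sqrt(rho) * z_block[bnum] + np.sqrt(1 - rho) * eps[idx]
                )
            for b, (amp, phase) in cfg.rhythmic_blocks.items():
                eta[block_index[b]] += amp * np.cos(2 * np.pi * (zt - phase) / 24.0)
            rows.append(eta)
            s += 1
            sample_ids.append(f"T{s:04d}")
            meta_rows.append(
                {
                    "sample-id": sample_ids[-1],
                    "subject-id": f"TCM{r+1:02d}",
                    "cage": f"C{r // 3 + 1:02d}",
                    "diet": diet,
                    "regime": regime,
                    "timepoint": f"ZT{zt:g}",
                    "zt_hours": float(zt),
                }
            )

    counts = _counts_from_eta(np.array(rows), cfg, rng)
    table = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample-id"),
                         columns=feature_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample-id")
    truth = SimTruth(
        blocks=pd.Series({f: b for f, b in zip(feature_ids, blocks)}, name="block"),
        block_effects=cfg.block_effects,
        rhythmic_blocks=cfg.rhythmic_blocks,
        phenotypes=cfg.phenotypes,
        unclassifiable=[],
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    truth: SimTruth,
    table: pd.DataFrame,
    cfg: SimConfig,
    seed=None,
    emit_glucose_series: bool = False,
):
    """Phenotype table: per sample, phenotype = intercept + sum beta_b *
    (block relative abundance) + Gaussian noise.

    With ``emit_glucose_series`` an OGTT-shaped glucose curve is also
    emitted per sample, scaled so its trapezoidal AUC over 0-120 min equals
    the sample's ``auc_ogtt`` value.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    rel = table.div(table.sum(axis=1), axis=0)
    out = pd.DataFrame(index=table.index)
    for name, model in cfg.phenotypes.items():
        value = np.full(len(table), float(model.get("intercept", 0.0)))
        for block, beta in model.get("beta", {}).items():
            members = truth.block_members(block)
            members = [m for m in members if m in rel.columns]
            if not members:
                raise ValueError(f"unknown block {block!r} in phenotype model")
            value += beta * rel[members].sum(axis=1).to_numpy()
        value += rng.normal(0.0, float(model.get("noise_sd", 0.0)), size=len(table))
        out[name] = value
    if emit_glucose_series and "auc_ogtt" in out:
        times = np.array([0.0, 15.0, 30.0, 60.0, 90.0, 120.0])
        shape = np.array([0.6, 1.6, 1.9, 1.3, 0.9, 0.7])
        shape = shape / np.trapezoid(shape, times)  # unit-AUC template
        for i, t in enumerate(times):
            out[f"glucose_{int(t)}min"] = out["auc_ogtt"].to_numpy() * shape[i]
    return out


def trapezoid_auc(values, times) -> float:
    """Trapezoidal area under a glucose series, in value-units x minutes."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two timepoints")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed (convenience for seed sweeps)."""
    return replace(cfg, seed=int(seed))
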