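"""Synthetic expression data with the structure REO analysis assumes.

The generator emulates the statistical signature of a normal-tissue
transcriptome cohort: a shared latent ordering of gene baseline levels (so
the within-sample orderings of most gene pairs are highly stable across
samples), multiplicative log-normal measurement noise, and — in one of two
sample groups — a small planted set of differentially expressed genes whose
baseline rank moves far enough to reverse a small fraction of the stable
pair orderings.

Baseline levels are geometrically spaced, mu_(rank) = exp(step * rank), so
the chance that noise flips an adjacent-rank pair within a sample is a single
number, Phi(-step / (sigma * sqrt(2))); with the defaults step = 0.3 and
sigma = 0.1 that is about 1.7%, and pairs further apart in rank flip
essentially never. REOs are invariant under monotone transforms, so this flip
probability is the only property of the noise model the analysis can see.

Ground truth (planted gene identities, directions, realized rank
displacements, and the exact reversal-pair count between the two noiseless
templates) is returned alongside the data for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ConfounderSpec", "GeneratorConfig", "SyntheticTruth", "generate", "scenario_suite"]


@dataclass(frozen=True)
class ConfounderSpec:
    """Per-group label probabilities and the age distribution.

    Probabilities are (group1, group2) tuples; ages are uniform over
    ``age_range`` in years, independent of expression.
    """

    p_male: tuple[float, float] = (0.5, 0.5)
    p_smoker: tuple[float, float] = (0.5, 0.5)
    p_white: tuple[float, float] = (0.5, 0.5)
    age_range: tuple[float, float] = (30.0, 80.0)


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 200
    samples_per_group: tuple[int, int] = (20, 20)
    noise_sigma: float = 0.1
    n_deg: int = 10
    rank_shift: int = 30
    deg_split: float = 0.5  # fraction of planted DEGs that go up in group 2
    template_log_step: float = 0.3
    group_labels: tuple[str, str] = ("group1", "group2")
    group_factor: str | None = None  # "smoking" | "sex" | "race": group IS that label
    sex_linked_cytobands: bool = False
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg cannot exceed n_genes")
        if self.n_deg > 0:
            if self.rank_shift < 1:
                raise ValueError("rank_shift must be >= 1")
            if self.rank_shift > self.n_genes - 1:
                raise ValueError(
                    "rank_shift exceeds n_genes - 1: no feasible displacement"
                )
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the parameter-recovery oracle for the pipeline."""

    degs: pd.DataFrame  # gene_id, direction, displacement (realized, >= rank_shift)
    reversal_pair_count: int  # exact count between the two noiseless templates
    config: GeneratorConfig
    cytobands: dict[str, str] | None = None


def _template_reversals(logmu1: np.ndarray, logmu2: np.ndarray) -> int:
    """Exhaustive count of pairs ordered oppositely by the two templates."""
    s1 = np.sign(logmu1[:, None] - logmu1[None, :])
    s2 = np.sign(logmu2[:, None] - logmu2[None, :])
    upper = np.triu_indices(len(logmu1), k=1)
    return int((s1[upper] != s2[upper]).sum())


def _plant_degs(rng, config, rank_of_gene, logmu_by_rank):
    """Choose planted genes and their moved baselines.

    Each planted gene's baseline is re-placed ``rank_shift + n_deg`` template
    positions away (capped at the rank range); the n_deg margin absorbs the
    at most n_deg - 1 positions that other planted genes' moves can shave off,
    so every realized displacement stays >= rank_shift. Moved baselines land
    at fractional offsets inside a target gap, distinct per gene and bounded
    away from the gap edges, so no two baselines ever tie.
    """
    g = config.n_genes
    s = min(config.rank_shift + config.n_deg, g - 1)
    n_up = int(round(config.n_deg * config.deg_split))
    n_down = config.n_deg - n_up
    order = rng.permutation(g)
    ups = [int(gi) for gi in order if rank_of_gene[gi] + s <= g - 1][:n_up]
    taken = set(ups)
    downs = [
        int(gi) for gi in order if rank_of_gene[gi] - s >= 0 and gi not in taken
    ][:n_down]
    if len(ups) < n_up or len(downs) < n_down:
        raise ValueError(
            "could not place all planted DEGs; reduce n_deg or rank_shift"
        )
    step = config.template_log_step
    chosen: list[tuple[int, str]] = []
    new_logmu: dict[int, float] = {}
    for members, direction in ((ups, "up"), (downs, "down")):
        for j, gi in enumerate(members):
            frac = step * (0.05 + 0.4 * (j + 1) / (len(members) + 1))
            r = rank_of_gene[gi]
            if direction == "up":
                new_logmu[gi] = logmu_by_rank[r + s] + frac
            else:
                new_logmu[gi] = logmu_by_rank[r - s] - frac
            chosen.append((gi, direction))
    return chosen, new_logmu


def _draw_labels(rng, n, p_true, true_label, false_label):
    return np.where(rng.random(n) < p_true, true_label, false_label)


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, metadata, truth) for a two-group cohort.

    Deterministic: identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n1, n2 = config.samples_per_group
    genes = np.array([f"g{i:05d}" for i in range(g)])
    # random rank assignment decouples gene-ID order from expression order
    rank_of_gene = rng.permutation(g)
    step = config.template_log_step
    logmu_by_rank = step * np.arange(g)
    logmu1 = logmu_by_rank[rank_of_gene]

    logmu2 = logmu1.copy()
    deg_rows = []
    if config.n_deg > 0:
        chosen, new_logmu = _plant_degs(rng, config, rank_of_gene, logmu_by_rank)
        for gi, direction in chosen:
            logmu2[gi] = new_logmu[gi]
        rank2 = np.empty(g, dtype=np.int64)
        rank2[np.argsort(logmu2, kind="stable")] = np.arange(g)
        for gi, direction in chosen:
            disp = int(abs(rank2[gi] - rank_of_gene[gi]))
            if disp < config.rank_shift:
                raise ValueError(
                    f"planted gene {genes[gi]} realized displacement {disp} "
                    f"< rank_shift {config.rank_shift}"
                )
            deg_rows.append(
                {
                    "gene_id": genes[gi],
                    "direction": "up_in_group2" if direction == "up" else "down_in_group2",
                    "displacement": disp,
                }
            )
    degs = pd.DataFrame(deg_rows, columns=["gene_id", "direction", "displacement"])
    degs = degs.sort_values("gene_id").reset_index(drop=True)

    n_total = n1 + n2
    noise = rng.normal(0.0, config.noise_sigma, size=(g, n_total))
    values = np.empty((g, n_total))
    values[:, :n1] = np.exp(logmu1[:, None] + noise[:, :n1])
    values[:, n1:] = np.exp(logmu2[:, None] + noise[:, n1:])
    samples = np.array([f"s{i:04d}" for i in range(n_total)])
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)

    meta = _metadata(rng, config, samples, n1, n2)
    cytobands = _cytobands(rng, genes, degs) if config.sex_linked_cytobands else None
    truth = SyntheticTruth(
        degs=degs,
        reversal_pair_count=_template_reversals(logmu1, logmu2),
        config=config,
        cytobands=cytobands,
    )
    return matrix, meta, truth


def _metadata(rng, config, samples, n1, n2):
    c = config.confounders
    group = np.array([config.group_labels[0]] * n1 + [config.group_labels[1]] * n2)
    sex = np.concatenate(
        [
            _draw_labels(rng, n1, c.p_male[0], "male", "female"),
            _draw_labels(rng, n2, c.p_male[1], "male", "female"),
        ]
    )
    smoking = np.concatenate(
        [
            _draw_labels(rng, n1, c.p_smoker[0], "smoker", "nonsmoker"),
            _draw_labels(rng, n2, c.p_smoker[1], "smoker", "nonsmoker"),
        ]
    )
    race = np.concatenate(
        [
            _draw_labels(rng, n1, c.p_white[0], "white", "black"),
            _draw_labels(rng, n2, c.p_white[1], "white", "black"),
        ]
    )
    age = np.round(rng.uniform(c.age_range[0], c.age_range[1], size=n1 + n2), 1)
    # when the grouping IS a confounding factor, that factor's column mirrors it
    if config.group_factor == "sex":
        sex = np.array(["female"] * n1 + ["male"] * n2)
    elif config.group_factor == "smoking":
        smoking = np.array(["nonsmoker"] * n1 + ["smoker"] * n2)
    elif config.group_factor == "race":
        race = np.array(["white"] * n1 + ["black"] * n2)
    elif config.group_factor is not None:
        raise ValueError(f"unknown group_factor {config.group_factor!r}")
    return pd.DataFrame(
        {"group": group, "sex": sex, "race": race, "smoking": smoking, "age": age},
        index=pd.Index(samples, name="sample_id"),
    )


def _cytobands(rng, genes, degs):
    """Sex-linked tagging: genes up in the male group get Y bands, up in the
    female group X bands, everything else a random autosomal band."""
    autosome_bands = [f"{c}q{a}{'.' + str(b) if b else ''}" for c in range(1, 23) for a, b in ((21, 1), (13, 0))]
    bands = {
        g: autosome_bands[int(i)]
        for g, i in zip(genes, rng.integers(0, len(autosome_bands), size=len(genes)))
    }
    y_bands = ["Yq11.221", "Yp11.2", "Yq11"]
    x_bands = ["Xp22.3", "Xp11.22", "Xq13.2"]
    for _, row in degs.iterrows():
        pool = y_bands if row["direction"] == "up_in_group2" else x_bands
        bands[row["gene_id"]] = pool[int(rng.integers(0, len(pool)))]
    return bands


def scenario_suite() -> dict[str, GeneratorConfig]:
    """Fixed-seed study conditions mirroring the confounder analyses at desk scale.

    - "smoking-like": many planted DEGs, the strongest ordering perturbation.
    - "sex-like": few DEGs, tagged with sex-chromosome cytobands; group = sex.
    - "race-like": very few DEGs.
    - "age-null": no planted effect; ages independent of expression.
    """
    return {
        "smoking-like": GeneratorConfig(
            n_genes=200,
            samples_per_group=(20, 20),
            n_deg=10,
            rank_shift=30,
            group_factor="smoking",
            group_labels=("nonsmoker", "smoker"),
            seed=20257,
        ),
        "sex-like": GeneratorConfig(
            n_genes=200,
            samples_per_group=(20, 20),
            n_deg=6,
            rank_shift=40,
            group_factor="sex",
            group_labels=("female", "male"),
            sex_linked_cytobands=True,
            seed=20258,
        ),
        "race-like": GeneratorConfig(
            n_genes=200,
            samples_per_group=(20, 20),
            n_deg=3,
            rank_shift=40,
            group_factor="race",
            group_labels=("white", "black"),
            seed=20259,
        ),
        # tighter spacing / higher noise so near-rank pairs split the cohort
        # into two sizeable REO groups — the substrate the age test needs
        "age-null": GeneratorConfig(
            n_genes=100,
            samples_per_group=(30, 30),
            n_deg=0,
            rank_shift=1,
            noise_sigma=0.3,
            template_log_step=0.15,
            confounders=ConfounderSpec(age_range=(37.0, 80.0)),
            seed=20260,
        ),
    }


def config_to_dict(config: GeneratorConfig) -> dict:
    """YAML/JSON-serialisable echo of a GeneratorConfig."""
    d = asdict(config)
    for key in ("samples_per_group", "group_labels"):
        d[key] = list(d[key])
    for key in ("p_male", "p_smoker", "p_white", "age_range"):
        d["confounders"][key] = list(d["confounders"][key])
    return d
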