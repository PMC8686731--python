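"""Synthetic metabarcoding experiments with known ground truth.

Emulates the structure of a two-primer-set fecal diet study: sex-structured
multi-prey diets with few common and many rare taxa, two technical
replicates per sample per primer set, extraction/PCR blanks, one
six-taxon mock-community sample per primer set, predator reads suppressed
to near zero, and low-rate read misassignment across samples (tag-jumping).

Generation order (fixed; all randomness flows through sub-streams spawned
from one seed, so the same seed gives bit-identical output):

1. draw each specimen's true diet by per-taxon, per-sex Bernoulli;
2. per primer set, draw clean read counts for present taxa from a shifted
   negative-binomial law scaled to the target depth (the abundance family
   is a placeholder — no part of acceptance depends on it);
3. thin replicate 2 against replicate 1 via ``replicate_dropout`` (done
   before per-dataset noise so that tag-jump strays and contamination are
   independent between replicates, which is what the replicate-consistency
   filter exploits);
4. per primer/replicate dataset: add predator reads at a near-zero rate,
   then move each read to a uniformly random *other* sample with
   probability ``tag_jump_rate`` (read totals are conserved);
5. populate negative controls with Poisson stray reads;
6. populate mock samples from the six mock taxa on top of any tag-jumped
   strays already delivered there (mock depth defaults to the mean
   specimen depth, so the stray fraction in the mock approximates the
   configured jump rate);
7. emit a taxonomy table whose confidences are high for prey/mock ASVs
   and below the order threshold for predator ASVs (the resolution stage
   therefore discards predator reads, mimicking "blocking worked").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    ConfigError,
    ReadMatrix,
    Role,
    SampleMeta,
    Sex,
    TaxonomyTable,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_experiment", "null_experiment"]

_ORDERS = ("Diptera", "Araneae", "Hemiptera", "Coleoptera", "Lepidoptera",
           "Hymenoptera", "Trichoptera", "Orthoptera")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    ``prevalence_beta`` gives the Beta law for per-taxon detection
    probabilities (defaults have mean ~0.05); draws are sorted descending
    and clipped at ``prevalence_max`` so there are a few common and many
    rare taxa.  ``sex_effect_taxa`` maps a taxon index to an explicit
    (female, male) prevalence pair, overriding the shared law.
    """

    n_female: int = 103
    n_male: int = 49
    n_taxa: int = 150
    prevalence_beta: tuple[float, float] = (0.5, 9.5)
    prevalence_max: float = 0.4
    sex_effect_taxa: Mapping[int, tuple[float, float]] = field(
        default_factory=dict
    )
    reads_per_sample: float = 5000.0
    overdispersion: float = 1.0
    tag_jump_rate: float = 0.005
    predator_read_mean: float = 3.0
    negative_contamination_mean: float = 0.2
    mock_taxa: tuple[str, ...] = tuple(f"Mock insect {i}" for i in range(1, 7))
    mock_depth: float | None = None
    replicate_dropout: float = 0.05
    n_offtarget_taxa: int = 5
    offtarget_rate: float = 0.02
    n_blanks: int = 3
    primer_sets: tuple[str, ...] = ("Leray", "ANML")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < len(self.sex_effect_taxa):
            raise ConfigError("more sex_effect_taxa than taxa")
        for idx, pair in self.sex_effect_taxa.items():
            if not 0 <= idx < self.n_taxa:
                raise ConfigError(f"sex_effect taxon index {idx} out of range")
            if not all(0.0 <= p <= 1.0 for p in pair):
                raise ConfigError("sex_effect prevalences must lie in [0,1]")
        for name, p in [
            ("tag_jump_rate", self.tag_jump_rate),
            ("replicate_dropout", self.replicate_dropout),
            ("offtarget_rate", self.offtarget_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.tag_jump_rate <= 0.05:
            raise ConfigError("tag_jump_rate must lie in [0, 0.05]")
        if self.reads_per_sample <= 0:
            raise ConfigError("reads_per_sample must be positive")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion must be positive")

    def clean(self) -> "SimConfig":
        """A noise-free variant: no jumping, contamination, predator reads
        or replicate dropout.  Used by exact-recovery tests."""
        from dataclasses import replace

        return replace(
            self,
            tag_jump_rate=0.0,
            predator_read_mean=0.0,
            negative_contamination_mean=0.0,
            replicate_dropout=0.0,
            n_offtarget_taxa=0,
        )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    presence: pd.DataFrame          # prey taxa (species keys) x specimens
    prevalence_female: "pd.Series[float]"
    prevalence_male: "pd.Series[float]"
    realized_tag_jump: dict[str, float]   # primer set -> jumped/total


def _taxon_key(label: str) -> str:
    return f"species:{label}"


def _draw_counts(rng: np.random.Generator, n: int, mu: float,
                 k: float) -> np.ndarray:
    """Shifted negative binomial: 1 + NB(mean mu-1, dispersion k).

    Presence always yields at least one read; detection failure is
    modeled separately (channel dropout / replicate dropout)."""
    m = max(mu - 1.0, 0.01)
    p = k / (k + m)
    return 1 + rng.negative_binomial(k, p, size=n)


def _tag_jump(rng: np.random.Generator, mat: np.ndarray,
              rate: float) -> tuple[np.ndarray, int]:
    """Move each read to a uniformly random other sample with prob ``rate``.

    Returns the perturbed matrix and the number of reads moved.  Totals
    per matrix are conserved."""
    if rate == 0.0:
        return mat, 0
    out = mat.copy()
    n_asv, n_samp = mat.shape
    jumps = rng.binomial(mat, rate)
    out -= jumps
    moved = 0
    rows, cols = np.nonzero(jumps)
    for r, c, k in zip(rows, cols, jumps[rows, cols]):
        # uniform over the n-1 other samples
        dest = rng.integers(0, n_samp - 1, size=k)
        dest[dest >= c] += 1
        np.add.at(out[r], dest, 1)
        moved += int(k)
    return out, moved


def simulate_experiment(
    config: SimConfig,
) -> tuple[
    dict[tuple[str, int], ReadMatrix],
    TaxonomyTable,
    list[SampleMeta],
    GroundTruth,
]:
    """Generate a full experiment: read matrices per (primer set, replicate),
    taxonomy, metadata, and the ground truth."""
    seq = np.random.SeedSequence(config.seed)
    (s_presence, s_counts, s_thin, s_noise, s_tax) = [
        np.random.default_rng(c) for c in seq.spawn(5)
    ]

    # --- identifiers -------------------------------------------------------
    females = [f"F{i:03d}" for i in range(1, config.n_female + 1)]
    males = [f"M{i:03d}" for i in range(1, config.n_male + 1)]
    specimens = females + males
    blanks = [f"BLK{i:02d}" for i in range(1, config.n_blanks + 1)]
    mock_sample = "MOCK01"
    samples = specimens + blanks + [mock_sample]
    spec_idx = np.arange(len(specimens))
    blank_idx = np.arange(len(specimens), len(specimens) + len(blanks))
    mock_idx = len(samples) - 1

    prey_labels = [f"Prey species {i:03d}" for i in range(config.n_taxa)]
    off_labels = [f"Fungal contaminant {i}" for i in range(config.n_offtarget_taxa)]

    # one ASV pair per prey taxon so the collapse step has work to do
    asv_rows: list[tuple[str, str, str, str, bool]] = []  # id, species, order, phylum, is_mock
    for i, lab in enumerate(prey_labels):
        order = _ORDERS[i % len(_ORDERS)]
        asv_rows.append((f"ASV_P{i:03d}a", lab, order, "Arthropoda", False))
        asv_rows.append((f"ASV_P{i:03d}b", lab, order, "Arthropoda", False))
    for i, lab in enumerate(off_labels):
        asv_rows.append((f"ASV_X{i:02d}", lab, "Hypocreales", "Ascomycota", False))
    for i, lab in enumerate(config.mock_taxa):
        asv_rows.append((f"ASV_M{i}", lab, _ORDERS[i % len(_ORDERS)],
                         "Arthropoda", True))
    asv_rows.append(("ASV_PRED", "Predator dragonfly", "Odonata",
                     "Arthropoda", False))
    asv_ids = [r[0] for r in asv_rows]
    asv_index = {a: i for i, a in enumerate(asv_ids)}

    # --- step 1: true diets ------------------------------------------------
    base = np.sort(
        np.clip(
            s_presence.beta(*config.prevalence_beta, size=config.n_taxa),
            0.0, config.prevalence_max,
        )
    )[::-1]
    prev_f = base.copy()
    prev_m = base.copy()
    for idx, (pf, pm) in config.sex_effect_taxa.items():
        prev_f[idx], prev_m[idx] = pf, pm
    p_per_spec = np.concatenate(
        [
            np.tile(prev_f, (config.n_female, 1)),
            np.tile(prev_m, (config.n_male, 1)),
        ]
    )  # specimen x taxon
    presence = (
        s_presence.random(p_per_spec.shape) < p_per_spec
    ).astype("int8").T  # taxon x specimen
    off_presence = (
        s_presence.random((config.n_offtarget_taxa, len(specimens)))
        < config.offtarget_rate
    ).astype("int8")

    expected_richness = max(1.0, float(base.sum()))
    mu = config.reads_per_sample / expected_richness
    mock_depth = (config.mock_depth if config.mock_depth is not None
                  else config.reads_per_sample)

    datasets: dict[tuple[str, int], ReadMatrix] = {}
    realized_jump: dict[str, float] = {}
    meta: list[SampleMeta] = []

    for primer in config.primer_sets:
        # --- step 2: clean counts (shared base for both replicates) -------
        base_mat = np.zeros((len(asv_ids), len(samples)), dtype=np.int64)

        def _fill(tax_presence: np.ndarray, id_a: list[str],
                  id_b: list[str] | None) -> None:
            rows, cols = np.nonzero(tax_presence)
            if rows.size == 0:
                return
            totals = _draw_counts(s_counts, rows.size, mu,
                                  config.overdispersion)
            if id_b is None:
                for r, c, t in zip(rows, cols, totals):
                    base_mat[asv_index[id_a[r]], spec_idx[c]] += t
            else:
                split = s_counts.binomial(totals, 0.5)
                for r, c, t, sa in zip(rows, cols, totals, split):
                    base_mat[asv_index[id_a[r]], spec_idx[c]] += sa
                    base_mat[asv_index[id_b[r]], spec_idx[c]] += t - sa

        _fill(presence, [f"ASV_P{i:03d}a" for i in range(config.n_taxa)],
              [f"ASV_P{i:03d}b" for i in range(config.n_taxa)])
        _fill(off_presence, [f"ASV_X{i:02d}" for i in range(config.n_offtarget_taxa)],
              None)

        # --- step 3: replicate thinning -----------------------------------
        rep_mats = {1: base_mat.copy(), 2: base_mat.copy()}
        if config.replicate_dropout > 0:
            drop = s_thin.random((config.n_taxa, len(specimens)))
            drop_mask = (presence == 1) & (drop < config.replicate_dropout)
            rows, cols = np.nonzero(drop_mask)
            for r, c in zip(rows, cols):
                rep_mats[2][asv_index[f"ASV_P{r:03d}a"], spec_idx[c]] = 0
                rep_mats[2][asv_index[f"ASV_P{r:03d}b"], spec_idx[c]] = 0

        moved_total, reads_total = 0, 0
        for rep in (1, 2):
            m = rep_mats[rep]
            # --- step 4: predator reads then tag-jumping ------------------
            if config.predator_read_mean > 0:
                m[asv_index["ASV_PRED"], spec_idx] += s_noise.poisson(
                    config.predator_read_mean, size=len(specimens)
                )
            pre_total = int(m.sum())
            m, moved = _tag_jump(s_noise, m, config.tag_jump_rate)
            moved_total += moved
            reads_total += pre_total
            # --- step 5: blank contamination ------------------------------
            if config.negative_contamination_mean > 0 and len(blanks):
                m[:, blank_idx] += s_noise.poisson(
                    config.negative_contamination_mean,
                    size=(len(asv_ids), len(blanks)),
                )
            # --- step 6: mock sample --------------------------------------
            mock_asv_rows = [asv_index[f"ASV_M{i}"]
                             for i in range(len(config.mock_taxa))]
            mock_counts = s_noise.multinomial(
                int(mock_depth), [1.0 / len(mock_asv_rows)] * len(mock_asv_rows)
            )
            m[mock_asv_rows, mock_idx] += mock_counts
            rep_mats[rep] = m

            datasets[(primer, rep)] = ReadMatrix(
                counts=pd.DataFrame(rep_mats[rep], index=asv_ids,
                                    columns=samples),
                primer_set=primer,
                replicate=rep,
            )
            for s in samples:
                if s in females:
                    role, sex = Role.SPECIMEN, Sex.FEMALE
                elif s in males:
                    role, sex = Role.SPECIMEN, Sex.MALE
                elif s == mock_sample:
                    role, sex = Role.MOCK, Sex.NA
                else:
                    role, sex = Role.NEGATIVE_CONTROL, Sex.NA
                meta.append(SampleMeta(sample_id=s, role=role, sex=sex,
                                       primer_set=primer, replicate=rep))
        realized_jump[primer] = (moved_total / reads_total
                                 if reads_total else 0.0)

    # --- step 7: taxonomy --------------------------------------------------
    tax_rows = {}
    for asv, species, order, phylum, is_mock in asv_rows:
        if asv == "ASV_PRED":
            # predator confidences sit below the order threshold: discarded
            c_sp = s_tax.uniform(0.01, 0.08)
            incr = s_tax.uniform(0.0, 0.03, size=3)
        else:
            c_sp = s_tax.uniform(0.55, 0.95)
            incr = s_tax.uniform(0.0, 0.04, size=3)
        c_ge = min(1.0, c_sp + incr[0])
        c_fa = min(1.0, c_ge + incr[1])
        c_or = min(1.0, c_fa + incr[2])
        genus = species.rsplit(" ", 1)[0]
        tax_rows[asv] = {
            "kingdom_label": "Animalia" if phylum == "Arthropoda" else "Fungi",
            "phylum_label": phylum,
            "order_label": order,
            "family_label": f"{order}idae",
            "genus_label": genus,
            "species_label": species,
            "kingdom_conf": 1.0,
            "phylum_conf": min(1.0, c_or + 0.02),
            "order_conf": c_or,
            "family_conf": c_fa,
            "genus_conf": c_ge,
            "species_conf": c_sp,
            "is_mock": is_mock,
        }
    taxonomy = TaxonomyTable(
        table=pd.DataFrame.from_dict(tax_rows, orient="index").loc[asv_ids]
    )

    truth = GroundTruth(
        presence=pd.DataFrame(
            presence, index=[_taxon_key(l) for l in prey_labels],
            columns=specimens,
        ),
        prevalence_female=pd.Series(prev_f, index=prey_labels),
        prevalence_male=pd.Series(prev_m, index=prey_labels),
        realized_tag_jump=realized_jump,
    )
    return datasets, taxonomy, meta, truth


def null_experiment(config: SimConfig):
    """Same generator with sex effects removed: both sexes share one
    prevalence vector."""
    from dataclasses import replace

    return simulate_experiment(replace(config, sex_effect_taxa={}))
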