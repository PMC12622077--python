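"""Synthetic whole-blood cohort generator.

Builds case/control cohorts with the statistical structure the downstream
analysis chain assumes: expression arises as a linear-scale mixture of
cell-type reference profiles (neutrophils dominating, with a group-shifted
neutrophil fraction), overlaid with plate/site batch effects, planted
disease effects (optionally restricted to one sex), technical replicates
whose noise is smaller than between-subject variation, and an MRI-like
feature block coupled to a latent disease-severity variable.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "ProbeFixture",
    "generate_signature_matrix",
    "generate_cohort",
    "generate_mri_block",
    "generate_probe_fixture",
]

#: Cell types of a coarse whole-blood decomposition; neutrophils first.
DEFAULT_CELL_TYPES = ("neutrophil", "t_cell", "b_cell", "monocyte", "nk_cell")

#: Dirichlet concentrations giving mean fractions ~(0.55, 0.25, 0.075, 0.10, 0.025),
#: the typical leukocyte composition of adult whole blood.
DEFAULT_DIRICHLET_BASE = (11.0, 5.0, 1.5, 2.0, 0.5)


@dataclass
class SignatureMatrix:
    """Linear-scale reference expression, genes x cell types.

    Each cell type owns a disjoint block of marker genes whose reference
    value exceeds the mean of the row over the other types by at least the
    construction fold.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_type_names: list[str]
    marker_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signature values must be 2-D (genes x cell types)")
        if np.any(self.values < 0):
            raise ValueError("signature values must be non-negative")
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_names)):
            raise ValueError("signature shape inconsistent with identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_type_names)


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study conditions the pipeline is meant to stress:
    a 346-subject balanced cohort on 18 plates across 3 clinical sites,
    a +0.05 neutrophil-fraction shift in cases, plate assignment mildly
    associated with diagnosis, 100 planted log2 disease effects of size 1
    (a quarter active in one sex only), and technical noise well below
    biological noise.
    """

    n_subjects: int = 346
    case_fraction: float = 0.5
    female_fraction: float = 0.55
    n_genes: int = 2000
    n_cell_types: int = 5
    dirichlet_base: tuple = DEFAULT_DIRICHLET_BASE
    neutrophil_shift: float = 0.05
    n_plates: int = 18
    n_sites: int = 3
    plate_location_sd: float = 0.5
    plate_scale_sd: float = 0.1
    plate_diagnosis_assoc: float = 0.3
    n_de_genes: int = 100
    de_effect_log2: float = 1.0
    sex_specific_fraction: float = 0.25
    biological_sd: float = 0.6
    technical_sd: float = 0.2
    n_replicate_subjects: int = 30
    mri_n_features: int = 136
    mri_loading: float = 0.5
    mri_latent_shift: float = 1.812
    age_mean_case: float = 76.0
    age_mean_control: float = 72.0
    age_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_fraction", "female_fraction", "sex_specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if len(self.dirichlet_base) != self.n_cell_types:
            raise ValueError("dirichlet_base length must equal n_cell_types")
        if any(a <= 0 for a in self.dirichlet_base):
            raise ValueError("dirichlet_base entries must be positive")

    def null(self) -> "SyntheticCohortConfig":
        """A copy with every class-associated and batch effect switched off."""
        return replace(
            self,
            neutrophil_shift=0.0,
            plate_location_sd=0.0,
            plate_scale_sd=0.0,
            plate_diagnosis_assoc=0.0,
            n_de_genes=0,
            age_mean_case=self.age_mean_control,
        )

    @classmethod
    def confounded_audit(cls, seed: int = 0) -> "SyntheticCohortConfig":
        """The standard confounded cohort the bias audit is benchmarked on.

        No planted disease genes (so the audit measures pure systematic
        bias), plate assignment associated with diagnosis at 0.3, a +0.05
        neutrophil-fraction shift in cases, and 500 subjects so that each
        of the 18 plates is populated well enough for stable empirical-
        Bayes batch estimates.
        """
        return cls(n_subjects=500, n_genes=2000, n_de_genes=0,
                   n_replicate_subjects=0, seed=seed)


@dataclass
class SyntheticCohort:
    """A generated cohort: expression plus ground truth."""

    expression: pd.DataFrame          # genes x samples, log2 scale
    metadata: pd.DataFrame            # one row per sample
    true_fractions: pd.DataFrame      # samples x cell types
    true_de_genes: pd.DataFrame       # gene, effect, sex restriction
    latent_severity: pd.Series        # per subject
    mri: pd.DataFrame                 # subjects x MRI-like features
    signature: SignatureMatrix
    config: SyntheticCohortConfig


@dataclass
class ProbeFixture:
    """Probe-level fixture with known filtering ground truth."""

    alignments: pd.DataFrame          # probe_id, n_genomic_matches, transcript_id, gene_symbol
    intensities: pd.DataFrame         # probes x samples, linear scale
    retained_truth: set               # probe ids passing both filters by construction
    transcripts_truth: dict           # transcript_id -> list of its probes


def generate_signature_matrix(
    n_genes: int,
    n_cell_types: int,
    markers_per_type: int,
    marker_fold: float,
    seed: int,
) -> SignatureMatrix:
    """Build a linear-scale reference signature with disjoint marker blocks.

    Non-marker entries are drawn log-normally around a per-gene baseline;
    the marker entry of a gene is set to at least ``marker_fold`` times the
    mean of its row over the other cell types.
    """
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError(
            f"marker demand {markers_per_type * n_cell_types} exceeds n_genes {n_genes}"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if n_cell_types <= len(DEFAULT_CELL_TYPES):
        cell_types = list(DEFAULT_CELL_TYPES[:n_cell_types])
    else:
        cell_types = list(DEFAULT_CELL_TYPES) + [
            f"cell_type_{i}" for i in range(len(DEFAULT_CELL_TYPES), n_cell_types)
        ]

    baseline = rng.lognormal(mean=3.0, sigma=0.8, size=n_genes)
    values = baseline[:, None] * rng.lognormal(mean=0.0, sigma=0.25, size=(n_genes, n_cell_types))

    marker_map: dict[str, list[str]] = {}
    g = 0
    for c, name in enumerate(cell_types):
        ids = []
        for _ in range(markers_per_type):
            other_mean = np.delete(values[g], c).mean()
            values[g, c] = marker_fold * other_mean * rng.uniform(1.0, 1.5)
            ids.append(gene_ids[g])
            g += 1
        marker_map[name] = ids
    return SignatureMatrix(values, gene_ids, cell_types, marker_map)


def _assign_plates(rng: np.random.Generator, is_case: np.ndarray, n_plates: int,
                   assoc: float, plate_shift: np.ndarray) -> np.ndarray:
    """Plate assignment with an optional diagnosis association.

    Cases are preferentially assigned to plates with a higher shared
    location offset (total-signal bright plates): a subject's plate
    probabilities are proportional to 1 + assoc * a_p * z_i with z_i = +1
    for cases and a_p the sign of the plate's shared offset (falling back
    to a half/half split when plate effects are switched off), so the
    batch structure itself carries diagnosis information.
    """
    if np.ptp(plate_shift) > 0:
        affinity = np.sign(plate_shift)
        affinity[affinity == 0] = 1.0
    else:
        affinity = np.where(np.arange(n_plates) < n_plates // 2, 1.0, -1.0)
    plates = np.empty(is_case.size, dtype=int)
    for i, case in enumerate(is_case):
        z = 1.0 if case else -1.0
        w = 1.0 + assoc * affinity * z
        w = np.clip(w, 0.0, None)
        plates[i] = rng.choice(n_plates, p=w / w.sum())
    return plates


def generate_cohort(config: SyntheticCohortConfig,
                    signature: Optional[SignatureMatrix] = None) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Expression model, per gene g and sample i::

        x_gi = log2( sum_c f_ic * S_gc * 2^effect_gi  + 1 )
               + gamma_{g,plate(i)} + delta_{g,plate(i)} * eps_gi
               + site_{g,site(i)} + b_gi

    where f_i. ~ Dirichlet(dirichlet_base) with the neutrophil concentration
    shifted in cases so the mean fraction moves by ``neutrophil_shift``;
    effect_gi equals the planted log2 effect for cases on disease genes
    (restricted to one sex for the sex-specific subset); eps is technical
    noise (redrawn for replicates), b is biological noise (shared by
    replicates of the same subject).
    """
    cfg = config
    n_cases = int(round(cfg.case_fraction * cfg.n_subjects))
    if cfg.case_fraction > 0 and n_cases < 1:
        raise ValueError("degenerate design: case_fraction * n_subjects < 1")
    rng = np.random.default_rng(cfg.seed)

    if signature is None:
        signature = generate_signature_matrix(
            n_genes=cfg.n_genes, n_cell_types=cfg.n_cell_types,
            markers_per_type=max(3, cfg.n_genes // (10 * cfg.n_cell_types)),
            marker_fold=8.0, seed=cfg.seed + 1,
        )
    S = signature.values
    n_genes = S.shape[0]
    gene_ids = signature.gene_ids

    # --- subjects -----------------------------------------------------------
    is_case = np.zeros(cfg.n_subjects, dtype=bool)
    is_case[:n_cases] = True
    rng.shuffle(is_case)
    is_female = rng.random(cfg.n_subjects) < cfg.female_fraction
    age_mean = np.where(is_case, cfg.age_mean_case, cfg.age_mean_control)
    age = rng.normal(age_mean, cfg.age_sd)
    age = np.clip(age, 50.0, 95.0)

    plate_shift = rng.normal(0.0, cfg.plate_location_sd, size=cfg.n_plates)
    plates = _assign_plates(rng, is_case, cfg.n_plates, cfg.plate_diagnosis_assoc,
                            plate_shift)
    # sites nest plates: plate p belongs to site p mod n_sites
    sites = plates % cfg.n_sites

    # --- cell fractions -----------------------------------------------------
    base = np.asarray(cfg.dirichlet_base, dtype=float)
    fractions = np.empty((cfg.n_subjects, cfg.n_cell_types))
    if cfg.neutrophil_shift != 0.0:
        # shift the neutrophil concentration so the case mean fraction moves
        # by neutrophil_shift while keeping the simplex constraint
        total = base.sum()
        mean0 = base[0] / total
        target = np.clip(mean0 + cfg.neutrophil_shift, 1e-6, 1 - 1e-6)
        # alpha0' solving alpha0'/(alpha0' + rest) = target
        rest = total - base[0]
        case_base = base.copy()
        case_base[0] = target * rest / (1.0 - target)
    else:
        case_base = base
    for i in range(cfg.n_subjects):
        fractions[i] = rng.dirichlet(case_base if is_case[i] else base)

    # --- planted disease effects -------------------------------------------
    de_idx = rng.choice(n_genes, size=cfg.n_de_genes, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)
    de_effect = de_sign * cfg.de_effect_log2
    n_sex = int(round(cfg.sex_specific_fraction * cfg.n_de_genes))
    sex_restrict = np.array([None] * cfg.n_de_genes, dtype=object)
    if n_sex:
        which = rng.choice(cfg.n_de_genes, size=n_sex, replace=False)
        halves = rng.random(n_sex) < 0.5
        sex_restrict[which] = np.where(halves, "F", "M")

    effect = np.zeros((n_genes, cfg.n_subjects))
    for k, g in enumerate(de_idx):
        active = is_case.copy()
        if sex_restrict[k] == "F":
            active &= is_female
        elif sex_restrict[k] == "M":
            active &= ~is_female
        effect[g, active] = de_effect[k]

    # --- batch effects ------------------------------------------------------
    # plate location = shared per-plate offset (a "plate total signal" shift
    # common to all genes, drawn above) plus an independent per-gene component
    gamma = plate_shift[None, :] + rng.normal(
        0.0, cfg.plate_location_sd, size=(n_genes, cfg.n_plates))
    delta = np.exp(rng.normal(0.0, cfg.plate_scale_sd, size=(n_genes, cfg.n_plates)))
    site_eff = rng.normal(0.0, cfg.plate_location_sd / 2.0, size=(n_genes, cfg.n_sites))
    if cfg.plate_location_sd == 0.0:
        site_eff[:] = 0.0

    bio = rng.normal(0.0, cfg.biological_sd, size=(n_genes, cfg.n_subjects))

    # --- latent severity & MRI ---------------------------------------------
    latent = cfg.mri_latent_shift * is_case.astype(float) + rng.normal(0.0, 1.0, cfg.n_subjects)
    subject_ids = [f"S{i:04d}" for i in range(cfg.n_subjects)]
    mri = generate_mri_block(cfg.n_subjects, latent, cfg,
                             rng=np.random.default_rng(cfg.seed + 2))
    mri.index = subject_ids

    # --- assemble samples (subjects + technical replicates) -----------------
    n_rep = min(cfg.n_replicate_subjects, cfg.n_subjects)
    rep_subjects = rng.choice(cfg.n_subjects, size=n_rep, replace=False)

    sample_subject = list(range(cfg.n_subjects)) + list(rep_subjects)
    sample_ids, rep_group = [], []
    seen: dict[int, int] = {}
    for subj in sample_subject:
        k = seen.get(subj, 0)
        seen[subj] = k + 1
        sample_ids.append(f"S{subj:04d}_r{k}")
        rep_group.append(f"S{subj:04d}")

    n_samples = len(sample_subject)
    subj_arr = np.asarray(sample_subject)
    lin = np.einsum("gc,ic->gi", S, fractions[subj_arr])
    lin = lin * np.exp2(effect[:, subj_arr])

    eps = rng.normal(0.0, cfg.technical_sd, size=(n_genes, n_samples))
    x = np.log2(lin + 1.0)
    x += gamma[:, plates[subj_arr]]
    x += delta[:, plates[subj_arr]] * eps
    x += site_eff[:, sites[subj_arr]]
    x += bio[:, subj_arr]

    expression = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": [f"S{s:04d}" for s in subj_arr],
        "diagnosis": np.where(is_case[subj_arr], "case", "control"),
        "sex": np.where(is_female[subj_arr], "F", "M"),
        "age": age[subj_arr],
        "plate": [f"plate{p:02d}" for p in plates[subj_arr]],
        "site": [f"site{s}" for s in sites[subj_arr]],
        "replicate_group": rep_group,
    }).set_index("sample_id")

    true_fractions = pd.DataFrame(
        fractions[subj_arr], index=sample_ids, columns=signature.cell_type_names
    )
    true_de = pd.DataFrame({
        "gene": [gene_ids[g] for g in de_idx],
        "effect_log2": de_effect,
        "sex_restricted": [s if s is not None else "" for s in sex_restrict],
    })
    latent_severity = pd.Series(latent, index=subject_ids, name="latent_severity")

    return SyntheticCohort(
        expression=expression, metadata=metadata, true_fractions=true_fractions,
        true_de_genes=true_de, latent_severity=latent_severity, mri=mri,
        signature=signature, config=cfg,
    )


def generate_mri_block(
    n_subjects: int,
    latent_severity: np.ndarray,
    config: SyntheticCohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """MRI-like feature block: feature_j = loading_j * t_i + unit noise.

    Loadings are drawn N(mri_loading, |mri_loading|/2 + 0.05); with
    ``mri_loading = 0`` every loading is zero and the block carries no
    diagnosis signal.
    """
    latent = np.asarray(latent_severity, dtype=float)
    if latent.shape[0] != n_subjects:
        raise ValueError("latent_severity length must equal n_subjects")
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent_severity must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    p = config.mri_n_features
    if config.mri_loading == 0.0:
        loadings = np.zeros(p)
    else:
        loadings = rng.normal(config.mri_loading, abs(config.mri_loading) / 2.0 + 0.05, p)
    noise = rng.normal(0.0, 1.0, size=(n_subjects, p))
    values = latent[:, None] * loadings[None, :] + noise
    cols = [f"mri_{j:03d}" for j in range(p)]
    return pd.DataFrame(values, columns=cols)


def generate_probe_fixture(
    n_transcripts: int,
    probes_per_transcript: int,
    multimap_fraction: float,
    uninformative_fraction: float,
    seed: int,
    n_samples: int = 8,
) -> ProbeFixture:
    """Probe alignment + intensity fixture with known filtering truth.

    Exactly ``floor(multimap_fraction * n_probes)`` probes are flagged with
    more than one genomic match, and ``floor(uninformative_fraction *
    n_probes)`` distinct probes are given a very low mean intensity and a
    near-zero coefficient of variation. The remaining probes have high
    signal and high CV, so the ground-truth retained set is unambiguous.
    """
    if not (0.0 <= multimap_fraction < 1.0 and 0.0 <= uninformative_fraction < 1.0):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_probes = n_transcripts * probes_per_transcript

    probe_ids = [f"P{i:05d}" for i in range(n_probes)]
    transcript_of = [f"ENST{t:08d}" for t in range(n_transcripts)
                     for _ in range(probes_per_transcript)]
    gene_of = [f"GENE{t // 2:05d}" for t in range(n_transcripts)
               for _ in range(probes_per_transcript)]

    n_multi = int(np.floor(multimap_fraction * n_probes))
    n_unin = int(np.floor(uninformative_fraction * n_probes))
    order = rng.permutation(n_probes)
    multi_idx = set(order[:n_multi].tolist())
    unin_idx = set(order[n_multi:n_multi + n_unin].tolist())

    n_matches = np.ones(n_probes, dtype=int)
    for i in multi_idx:
        n_matches[i] = int(rng.integers(2, 6))

    intensities = np.empty((n_probes, n_samples))
    for i in range(n_probes):
        if i in unin_idx:
            base = rng.uniform(0.8, 1.2)          # very low signal
            intensities[i] = base * (1.0 + rng.normal(0.0, 0.01, n_samples))
        else:
            base = rng.uniform(50.0, 500.0)       # clearly expressed
            intensities[i] = base * np.exp(rng.normal(0.0, 0.4, n_samples))
    intensities = np.abs(intensities)

    alignments = pd.DataFrame({
        "probe_id": probe_ids,
        "n_genomic_matches": n_matches,
        "transcript_id": transcript_of,
        "gene_symbol": gene_of,
    })
    intens = pd.DataFrame(intensities, index=probe_ids,
                          columns=[f"sample{j}" for j in range(n_samples)])
    retained = {probe_ids[i] for i in range(n_probes)
                if i not in multi_idx and i not in unin_idx}
    transcripts_truth: dict[str, list[str]] = {}
    for pid, tid in zip(probe_ids, transcript_of):
        transcripts_truth.setdefault(tid, []).append(pid)
    return ProbeFixture(alignments, intens, retained, transcripts_truth)
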