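"""Class-conditional generator of realistic LC-MS feature tables.

The generator emulates the structure an untargeted HILIC metabolomics
export shows after feature finding: a large unidentified majority (~94% of
features), a small identified subset of which roughly 23% are lipids,
m/z values spanning ~70-800 Th, early-eluting lipid-like compounds (low
percent-aqueous at elution), retention-time artifacts outside the usable
1-14 min window, and a share of identified metabolites detected in both
ionization polarities.

Predictors are drawn class-conditionally: the gradient composition at
elution from truncated normals (lipids concentrated at low %A, non-lipids
broad and higher), m/z from truncated normals with a weaker class gap.
Retention times are derived by inverting the gradient ramp, so annotating
the generated table with the same program reproduces the drawn
compositions exactly — the loop is closed for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .curation import DEFAULT_LIPID_CLASS, LABEL_LIPID, LABEL_NON_LIPID
from .gradient import GradientProgram
from .io import FeatureRecord, FeatureTable, TaxonomyMap

__all__ = ["SyntheticConfig", "generate", "scenario", "SCENARIO_NAMES"]

# Non-lipid identifications rotate through real HMDB super-class names,
# organic acids first (the largest class among typical identifications).
_NON_LIPID_CLASSES = (
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Organic oxygen compounds",
    "Benzenoids",
    "Nucleosides, nucleotides, and analogues",
    "Organic nitrogen compounds",
    "Alkaloids and derivatives",
)

# Fraction of records drawn in negative ionization mode; negative-mode
# coverage dominates in the emulated acquisitions.
_NEGATIVE_MODE_RATE = 0.6

_TOTAL_RUN_MINUTES = 20.0  # ramp + isocratic hold + re-equilibration


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the class-conditional feature generator."""

    n_features: int = 5000
    identified_fraction: float = 0.06
    lipid_prevalence: float = 0.23
    lipid_pct_a_mean: float = 23.0
    lipid_pct_a_sd: float = 2.0
    nonlipid_pct_a_mean: float = 45.0
    nonlipid_pct_a_sd: float = 12.0
    mz_range: tuple[float, float] = (70.0, 800.0)
    lipid_mz_mean: float = 550.0
    nonlipid_mz_mean: float = 280.0
    mz_sd: float = 120.0
    dual_polarity_rate: float = 0.2
    artifact_rate: float = 0.05
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identified_fraction", "lipid_prevalence", "dual_polarity_rate", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.lipid_pct_a_sd <= 0 or self.nonlipid_pct_a_sd <= 0 or self.mz_sd <= 0:
            raise ValueError("standard deviations must be positive")
        lo, hi = self.mz_range
        if not (0 < lo < hi):
            raise ValueError("mz_range must be positive and ordered")
        if self.n_features < 1:
            raise ValueError("n_features must be at least 1")

    def class_pct_a_means(self) -> tuple[float, float]:
        """(lipid, non-lipid) %A means after separation scaling.

        The gap between the class means is multiplied by ``separation``,
        anchored at the lipid mean: lipid-like compounds elute at the start
        of the ramp whatever the chemistry of the rest, so widening or
        narrowing the gap moves only the non-lipid mean.  This also keeps
        the scaled means inside the gradient's composition range for the
        documented presets.
        """
        gap = self.nonlipid_pct_a_mean - self.lipid_pct_a_mean
        return (
            self.lipid_pct_a_mean,
            self.lipid_pct_a_mean + gap * self.separation,
        )


def _trunc_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(
    config: SyntheticConfig, program: GradientProgram | None = None
) -> tuple[FeatureTable, TaxonomyMap, dict[str, str]]:
    """Draw a feature table, its taxonomy extract, and the identified truth map.

    Returns (table, taxonomy, truth) where ``truth`` maps the feature_id of
    every identified record (including dual-polarity duplicates) to its
    generated label.  Fully reproducible from ``config.seed``.
    """
    if program is None:
        program = GradientProgram()
    rng = np.random.default_rng(config.seed)
    lo_a, hi_a = program.composition_range
    lipid_mean, nonlipid_mean = config.class_pct_a_means()
    if not (lo_a <= lipid_mean <= hi_a and lo_a <= nonlipid_mean <= hi_a):
        raise ValueError(
            f"class %A means ({lipid_mean:.1f}, {nonlipid_mean:.1f}) fall outside "
            f"the program composition range [{lo_a}, {hi_a}] after separation scaling"
        )

    n = config.n_features
    identified = rng.random(n) < config.identified_fraction
    is_lipid = rng.random(n) < config.lipid_prevalence  # latent class for everyone

    pct_a = np.empty(n)
    mz = np.empty(n)
    for lipid_flag, pa_mean, pa_sd, mz_mean in (
        (True, lipid_mean, config.lipid_pct_a_sd, config.lipid_mz_mean),
        (False, nonlipid_mean, config.nonlipid_pct_a_sd, config.nonlipid_mz_mean),
    ):
        mask = is_lipid == lipid_flag
        k = int(mask.sum())
        if k:
            pct_a[mask] = _trunc_normal(rng, pa_mean, pa_sd, lo_a, hi_a, k)
            mz[mask] = _trunc_normal(
                rng, mz_mean, config.mz_sd, config.mz_range[0], config.mz_range[1], k
            )

    rt = np.asarray(program.time_at_composition(pct_a), dtype=float)
    # keep generated elution times inside the usable window so that only
    # injected artifacts fall outside it
    rt = np.clip(rt, 1.02, 13.98)
    polarity = np.where(rng.random(n) < _NEGATIVE_MODE_RATE, "negative", "positive")

    records: list[FeatureRecord] = []
    taxonomy: dict[str, str] = {}
    truth: dict[str, str] = {}
    next_accession = 5000001
    nonlipid_rotation = 0

    ident_meta: list[tuple[int, str, str]] = []  # (row, accession, label)
    for i in range(n):
        fid = f"F{i + 1:06d}"
        annotation = None
        accession = None
        if identified[i]:
            accession = f"HMDB{next_accession:07d}"
            next_accession += 1
            label = LABEL_LIPID if is_lipid[i] else LABEL_NON_LIPID
            if is_lipid[i]:
                taxonomy[accession] = DEFAULT_LIPID_CLASS
            else:
                taxonomy[accession] = _NON_LIPID_CLASSES[
                    nonlipid_rotation % len(_NON_LIPID_CLASSES)
                ]
                nonlipid_rotation += 1
            annotation = f"synthetic-metabolite-{accession[4:]}"
            truth[fid] = label
            ident_meta.append((i, accession, label))
        records.append(
            FeatureRecord(
                feature_id=fid,
                mz=float(mz[i]),
                rt_min=float(rt[i]),
                polarity=str(polarity[i]),
                annotation=annotation,
                hmdb_id=accession,
            )
        )

    # dual-polarity duplicates of identified metabolites, m/z jittered a few ppm
    dup_count = 0
    for i, accession, label in ident_meta:
        if rng.random() < config.dual_polarity_rate:
            dup_count += 1
            fid = f"F{n + dup_count:06d}"
            other = "positive" if records[i].polarity == "negative" else "negative"
            jitter = 1.0 + rng.normal(0.0, 5e-6)
            records.append(
                FeatureRecord(
                    feature_id=fid,
                    mz=float(records[i].mz * jitter),
                    rt_min=float(np.clip(records[i].rt_min + rng.normal(0.0, 0.02), 1.02, 13.98)),
                    polarity=other,
                    annotation=records[i].annotation,
                    hmdb_id=accession,
                )
            )
            truth[fid] = label

    # retention-time artifacts: false detections during setup/washing
    for idx in range(len(records)):
        if rng.random() < config.artifact_rate:
            if rng.random() < 0.5:
                bad_rt = float(rng.uniform(0.0, 1.0))  # (0, 1]: dead-time region
                bad_rt = 1.0 if bad_rt == 0.0 else bad_rt
            else:
                bad_rt = float(rng.uniform(14.0, _TOTAL_RUN_MINUTES))
            records[idx] = replace(records[idx], rt_min=bad_rt)

    table = FeatureTable(
        tuple(records), provenance=f"synthetic(seed={config.seed})"
    )
    return table, TaxonomyMap(taxonomy), truth


SCENARIO_NAMES = ("default", "separable", "overlapping", "balanced")


def scenario(name: str, **overrides) -> SyntheticConfig:
    """Documented presets over the default configuration.

    - ``default``: the reference structure (23% lipids among identified,
      6% identified, overlapping but separable classes).
    - ``separable``: class %A means pulled apart (separation 2.0) so every
      reasonable model family recovers the classes nearly perfectly.
    - ``overlapping``: means pushed together (separation 0.3); no family
      should classify perfectly.
    - ``balanced``: lipid prevalence 0.5, making the balancing
      preprocessor a no-op in expectation.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    base = SyntheticConfig()
    if name == "separable":
        base = replace(base, separation=2.0)
    elif name == "overlapping":
        base = replace(base, separation=0.3)
    elif name == "balanced":
        base = replace(base, lipid_prevalence=0.5)
    if overrides:
        base = replace(base, **overrides)
    return base
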