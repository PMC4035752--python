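"""Synthetic multi-caller somatic-mutation validation datasets.

Generates union-ascertained datasets with the structure of a TCGA
endometrial-style three-caller validation study: roughly 4,400 validated
union sites at ~78% true-mutation prevalence, one liberal caller, one
strict caller, and one weaker caller whose quality score and filter
outcomes are also emitted. Candidate sites carry tumor/normal depth,
tumor/normal variant allele fraction and a substitution type; caller
errors may depend on these features through log-odds modifiers, which is
exactly the regime in which feature-weighted stacking can pay off.

All randomness flows from a single seed through named substreams, so
adding a caller or a filter does not perturb the other components' draws.
No reference genome is involved: sites are abstract (chrom, pos, ref, alt)
keys.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from callstack.data_model import (
    SUBSTITUTION_TYPES,
    CallDataset,
    DataError,
    Site,
    write_caller_vcf,
)
from callstack.venn import all_statuses

# reference points used to put features on a roughly unit log-odds scale
_DEPTH_TUMOR_REF = 90.0
_DEPTH_NORMAL_REF = 60.0


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, component name)."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _feature_z(name: str, feats: Mapping[str, np.ndarray]) -> np.ndarray:
    """Standardized transform of a feature for log-odds modifiers."""
    if name == "depth_tumor":
        return (np.log2(feats["depth_tumor"] + 1.0) - np.log2(_DEPTH_TUMOR_REF + 1.0)) / 0.6
    if name == "depth_normal":
        return (np.log2(feats["depth_normal"] + 1.0) - np.log2(_DEPTH_NORMAL_REF + 1.0)) / 0.6
    if name == "vaf_tumor":
        return (feats["vaf_tumor"] - 0.25) / 0.15
    if name == "vaf_normal":
        return (feats["vaf_normal"] - 0.02) / 0.03
    raise DataError(f"unknown feature {name!r} in modifier")


@dataclass(frozen=True)
class QualityModel:
    """Continuous mutation-quality score: intercept + truth shift + VAF term + noise."""

    intercept: float = 20.0
    truth_shift: float = 15.0
    vaf_tumor_coef: float = 20.0
    noise_sd: float = 8.0


@dataclass(frozen=True)
class FilterModel:
    """One opaque binary filter: per-site probability of FAILING.

    ``P(fail) = sigmoid(logit(fail_rate_true) + (1 - truth) * artifact_shift
    + sum feature_coefs * z)``; the flag recorded is pass = 1 - fail.
    """

    name: str
    fail_rate_true: float = 0.05
    artifact_shift: float = 0.0
    feature_coefs: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class CallerProfile:
    """How one caller behaves given the hidden truth and the site features.

    ``sensitivity_base``/``specificity_base`` set the call probability at
    reference feature values; ``feature_modifiers`` (true sites) and
    ``fp_feature_modifiers`` (artifact sites) shift it on the log-odds
    scale. If ``filter_models`` are present the final call additionally
    requires every filter to pass, and extras (quality + flags) are
    emitted for the whole union universe.
    """

    name: str
    sensitivity_base: float = 0.9
    specificity_base: float = 0.9
    feature_modifiers: tuple[tuple[str, float], ...] = ()
    fp_feature_modifiers: tuple[tuple[str, float], ...] = ()
    quality_model: QualityModel | None = None
    filter_models: tuple[FilterModel, ...] = ()

    def __post_init__(self) -> None:
        for p in (self.sensitivity_base, self.specificity_base):
            if not 0.0 <= p <= 1.0:
                raise DataError("base probabilities must lie in [0, 1]")

    def call_prob(self, truth: np.ndarray, feats: Mapping[str, np.ndarray]) -> np.ndarray:
        """Per-site probability of the core detection (before filters)."""
        eta_t = _logit(self.sensitivity_base)
        eta_f = _logit(1.0 - self.specificity_base)
        eta = np.where(truth == 1, eta_t, eta_f).astype(float)
        for name, coef in self.feature_modifiers:
            eta = eta + np.where(truth == 1, coef * _feature_z(name, feats), 0.0)
        for name, coef in self.fp_feature_modifiers:
            eta = eta + np.where(truth == 1, 0.0, coef * _feature_z(name, feats))
        return _sigmoid(eta)


#: Substitution-type frequencies with the C>T / G>A dominance typical of
#: hypermutated endometrial tumors.
DEFAULT_SUBSTITUTION_FREQS: tuple[tuple[str, float], ...] = (
    ("A>C", 0.02), ("A>G", 0.07), ("A>T", 0.02),
    ("C>A", 0.08), ("C>G", 0.03), ("C>T", 0.28),
    ("G>A", 0.28), ("G>C", 0.03), ("G>T", 0.08),
    ("T>A", 0.02), ("T>C", 0.07), ("T>G", 0.02),
)


@dataclass
class SimConfig:
    """Study conditions for one simulated validation dataset.

    Defaults are sized to the motivating study: three callers whose
    ascertained union is ~4,400 sites with ~78% of them true somatic
    mutations — a liberal caller (high sensitivity, many false calls), a
    weaker caller with quality scores and filters, and a strict caller.
    """

    n_candidate_sites: int = 8400
    prevalence: float = 0.415
    caller_profiles: tuple[CallerProfile, ...] = ()
    substitution_freqs: tuple[tuple[str, float], ...] = DEFAULT_SUBSTITUTION_FREQS
    depth_tumor_mean: float = _DEPTH_TUMOR_REF
    depth_normal_mean: float = _DEPTH_NORMAL_REF
    depth_dispersion: float = 5.0
    clonal_vaf: float = 0.35
    subclonal_vaf: float = 0.15
    subclonal_fraction: float = 0.3
    vaf_concentration: float = 40.0
    artifact_vaf_alpha: float = 1.2
    artifact_vaf_beta: float = 18.0
    shared_artifact_rate: float = 0.0
    shared_artifact_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.caller_profiles:
            self.caller_profiles = default_caller_profiles()
        if not 0.0 < self.prevalence < 1.0:
            raise DataError("prevalence must lie in (0, 1)")
        if len(self.caller_profiles) < 2:
            raise DataError("need at least two callers")
        freqs = dict(self.substitution_freqs)
        if set(freqs) != set(SUBSTITUTION_TYPES) or abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise DataError("substitution frequencies must cover all 12 types and sum to 1")


def default_caller_profiles() -> tuple[CallerProfile, ...]:
    """Three callers shaped like the motivating study's A, B and C.

    Under conditional independence these bases put the ascertained union
    near 78% true mutations with marginal operating points close to
    (68, 96), (33, 63) and (4, 66) percent FP/TP. Mild feature modifiers
    make sensitivity drop at low depth or low tumor VAF, the
    feature-dependent error structure stacking exploits.
    """
    return (
        CallerProfile(
            name="A", sensitivity_base=0.96, specificity_base=0.865,
            feature_modifiers=(("depth_tumor", 0.6),),
        ),
        CallerProfile(
            name="B", sensitivity_base=0.68, specificity_base=0.91,
            feature_modifiers=(("vaf_tumor", 0.5),),
            quality_model=QualityModel(),
            filter_models=(
                FilterModel("strand_bias", fail_rate_true=0.03, artifact_shift=2.0),
                FilterModel("clustered_events", fail_rate_true=0.04, artifact_shift=1.0),
            ),
        ),
        CallerProfile(
            name="C", sensitivity_base=0.66, specificity_base=0.9926,
            feature_modifiers=(("vaf_tumor", 0.8), ("depth_tumor", 0.4)),
        ),
    )


def complementary_preset(n_candidate_sites: int = 6000) -> SimConfig:
    """Two callers with opposite depth-dependent strengths plus an average one.

    Caller HI is reliable on high-coverage sites and poor on low coverage;
    caller LO is the mirror image; caller MID is unconditionally mediocre.
    No single caller dominates, but which caller to trust is readable off
    the depth feature — the regime where the feature-weighted stacker
    should beat every individual caller's operating point.
    """
    return SimConfig(
        n_candidate_sites=n_candidate_sites,
        prevalence=0.5,
        caller_profiles=(
            CallerProfile(name="HI", sensitivity_base=0.75, specificity_base=0.88,
                          feature_modifiers=(("depth_tumor", 2.2),),
                          fp_feature_modifiers=(("depth_tumor", -1.0),)),
            CallerProfile(name="LO", sensitivity_base=0.75, specificity_base=0.88,
                          feature_modifiers=(("depth_tumor", -2.2),),
                          fp_feature_modifiers=(("depth_tumor", 1.0),)),
            CallerProfile(name="MID", sensitivity_base=0.70, specificity_base=0.85),
        ),
    )


def planted_filter_preset(n_candidate_sites: int = 6000) -> SimConfig:
    """A caller whose false calls concentrate in the fail state of one filter.

    The target caller "B" emits a noisy quality score; its "strand_bias"
    filter fails mostly on artifacts (informative), while "proximal_gap"
    fails indiscriminately and discards true mutations too. A refinement
    model that reads the flags can recover those true mutations, so its
    ROC should beat quality-only ranking.
    """
    return SimConfig(
        n_candidate_sites=n_candidate_sites,
        prevalence=0.5,
        caller_profiles=(
            CallerProfile(name="A", sensitivity_base=0.92, specificity_base=0.75),
            CallerProfile(
                name="B", sensitivity_base=0.92, specificity_base=0.85,
                quality_model=QualityModel(noise_sd=12.0, truth_shift=10.0),
                filter_models=(
                    FilterModel("strand_bias", fail_rate_true=0.04, artifact_shift=3.0),
                    FilterModel("proximal_gap", fail_rate_true=0.30, artifact_shift=0.3),
                ),
            ),
            CallerProfile(name="C", sensitivity_base=0.70, specificity_base=0.97),
        ),
    )


# ---------------------------------------------------------------------------


def _draw_features(config: SimConfig, truth: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = len(truth)
    disp = config.depth_dispersion

    def negbin(mean):
        return rng.negative_binomial(disp, disp / (disp + mean), size=n) + 8

    kappa = config.vaf_concentration
    is_sub = rng.random(n) < config.subclonal_fraction
    mu = np.where(is_sub, config.subclonal_vaf, config.clonal_vaf)
    vaf_true = rng.beta(mu * kappa, (1 - mu) * kappa)
    vaf_art = rng.beta(config.artifact_vaf_alpha, config.artifact_vaf_beta, size=n)
    vaf_normal_true = rng.beta(0.6, 60.0, size=n)
    vaf_normal_art = rng.beta(1.0, 25.0, size=n)
    return {
        "depth_tumor": negbin(config.depth_tumor_mean).astype(float),
        "depth_normal": negbin(config.depth_normal_mean).astype(float),
        "vaf_tumor": np.where(truth == 1, vaf_true, vaf_art),
        "vaf_normal": np.where(truth == 1, vaf_normal_true, vaf_normal_art),
    }


def simulate_dataset(config: SimConfig, seed: int | None = None) -> CallDataset:
    """Draw one union-ascertained dataset with hidden truth as labels.

    Candidate sites get features and a truth flag; each caller's core call
    is Bernoulli with its profile's (feature-adjusted) probability, its
    filters fail independently per their models, and the final call
    requires core detection plus all filters passing. Candidates no caller
    called are discarded (union ascertainment). Fully reproducible from
    the seed.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    n = config.n_candidate_sites
    truth = (_rng(config.seed, "truth").random(n) < config.prevalence).astype(np.int8)
    feats = _draw_features(config, truth, _rng(config.seed, "features"))

    freqs = dict(config.substitution_freqs)
    subs = _rng(config.seed, "substitution").choice(
        SUBSTITUTION_TYPES, size=n, p=[freqs[s] for s in SUBSTITUTION_TYPES]
    )

    shared = np.zeros(n)
    if config.shared_artifact_rate > 0:
        deceptive = _rng(config.seed, "shared").random(n) < config.shared_artifact_rate
        shared = np.where((truth == 0) & deceptive, config.shared_artifact_shift, 0.0)

    caller_names = [p.name for p in config.caller_profiles]
    calls = np.zeros((n, len(caller_names)), dtype=np.int8)
    extras_raw: dict[str, dict] = {}
    for k, profile in enumerate(config.caller_profiles):
        p_call = profile.call_prob(truth, feats)
        if config.shared_artifact_rate > 0:
            p_call = _sigmoid(np.log(p_call / (1 - p_call)) + shared)
        core = _rng(config.seed, f"caller:{profile.name}").random(n) < p_call
        all_pass = np.ones(n, dtype=bool)
        flags = {}
        for fm in profile.filter_models:
            eta = _logit(fm.fail_rate_true) + (1 - truth) * fm.artifact_shift
            for fname, coef in fm.feature_coefs:
                eta = eta + coef * _feature_z(fname, feats)
            fail = _rng(config.seed, f"filter:{profile.name}:{fm.name}").random(n) < _sigmoid(eta)
            flags[fm.name] = (~fail).astype(np.int8)
            all_pass &= ~fail
        calls[:, k] = (core & all_pass).astype(np.int8)
        if profile.quality_model is not None:
            qm = profile.quality_model
            noise = _rng(config.seed, f"quality:{profile.name}").normal(0.0, qm.noise_sd, size=n)
            quality = qm.intercept + qm.truth_shift * truth + qm.vaf_tumor_coef * feats["vaf_tumor"] + noise
            extras_raw[profile.name] = {"quality": quality, "flags": flags}

    ascertained = calls.any(axis=1)
    if not ascertained.any():
        raise DataError(
            "no candidate site was called by any caller; "
            "check sensitivity/specificity bases and n_candidate_sites"
        )
    idx = np.flatnonzero(ascertained)
    sites = [
        Site("1", 1000 + int(i), subs[i][0], subs[i][2])
        for i in idx
    ]
    features = pd.DataFrame(
        {
            "depth_tumor": feats["depth_tumor"][idx],
            "depth_normal": feats["depth_normal"][idx],
            "vaf_tumor": feats["vaf_tumor"][idx],
            "vaf_normal": feats["vaf_normal"][idx],
            "substitution": subs[idx],
        }
    )
    extras = {}
    for name, d in extras_raw.items():
        cols = {"quality": d["quality"][idx]}
        for fname, fl in d["flags"].items():
            cols[fname] = fl[idx]
        extras[name] = pd.DataFrame(cols)
    return CallDataset(
        sites=sites,
        caller_names=caller_names,
        calls=calls[idx],
        labels=truth[idx],
        features=features,
        extras=extras,
    )


def _homogeneous_call_probs(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-caller P(call | truth) and P(call | artifact) for modifier-free profiles."""
    s, q = [], []
    for p in config.caller_profiles:
        if p.feature_modifiers or p.fp_feature_modifiers:
            raise DataError("no closed form with feature modifiers; use simulate_dataset")
        if any(fm.feature_coefs for fm in p.filter_models):
            raise DataError("no closed form with feature-dependent filters")
        pass_t = pass_f = 1.0
        for fm in p.filter_models:
            pass_t *= 1.0 - fm.fail_rate_true
            pass_f *= 1.0 - _sigmoid(_logit(fm.fail_rate_true) + fm.artifact_shift)
        s.append(p.sensitivity_base * pass_t)
        q.append((1.0 - p.specificity_base) * pass_f)
    return np.array(s), np.array(q)


def analytic_ascertained_rates(config: SimConfig) -> dict:
    """Exact per-status masses and validation rates for homogeneous profiles.

    Only valid when no profile uses feature modifiers or feature-dependent
    filters (callers are then conditionally independent given truth with
    constant call probabilities). Serves as the closed-form oracle against
    which the simulator's empirical partition is tested.

    Returns a dict with ``status_mass`` and ``status_val_rate`` keyed by
    status label, plus ``p_ascertained`` and ``ascertained_prevalence``.
    """
    if config.shared_artifact_rate > 0:
        raise DataError("no closed form with shared-artifact correlation")
    s, q = _homogeneous_call_probs(config)
    pi = config.prevalence
    caller_names = [p.name for p in config.caller_profiles]
    mass, rate = {}, {}
    total = 0.0
    total_true = 0.0
    for status in all_statuses(caller_names):
        m = np.array(status.mask)
        p_t = float(np.prod(np.where(m == 1, s, 1 - s)))
        p_f = float(np.prod(np.where(m == 1, q, 1 - q)))
        joint_t = pi * p_t
        joint = joint_t + (1 - pi) * p_f
        mass[status.label] = joint
        rate[status.label] = 100.0 * joint_t / joint if joint > 0 else None
        total += joint
        total_true += joint_t
    if total == 0:
        raise DataError("ascertainment probability is zero under this configuration")
    return {
        "status_mass": {k: v / total for k, v in mass.items()},
        "status_val_rate": rate,
        "p_ascertained": total,
        "ascertained_prevalence": total_true / total,
    }


# ---------------------------------------------------------------------------


def write_dataset_files(dataset: CallDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as the package's own input files.

    Emits one VCF per caller, ``validation.tsv``, ``features.tsv`` and (if
    extras exist) ``extras.tsv``, i.e. exactly the formats the readers in
    :mod:`callstack.data_model` consume — the fixture generator doubles as
    a round-trip test of the interchange formats.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for k, name in enumerate(dataset.caller_names):
        p = out_dir / f"caller_{name}.vcf"
        write_caller_vcf([s for s, c in zip(dataset.sites, dataset.calls[:, k]) if c], p)
        paths[f"vcf:{name}"] = p

    key = dataset.to_frame()[["chrom", "pos", "ref", "alt"]]
    if dataset.labels is not None:
        val = key.copy()
        val["status"] = np.where(dataset.labels == 1, "somatic", "non-somatic")
        paths["validation"] = out_dir / "validation.tsv"
        val.to_csv(paths["validation"], sep="\t", index=False)
    if dataset.features is not None:
        feat = pd.concat(
            [key, dataset.features[["depth_tumor", "depth_normal", "vaf_tumor", "vaf_normal"]]], axis=1
        )
        feat["depth_tumor"] = feat["depth_tumor"].astype("Int64")
        feat["depth_normal"] = feat["depth_normal"].astype("Int64")
        paths["features"] = out_dir / "features.tsv"
        feat.to_csv(paths["features"], sep="\t", index=False, na_rep=".")
    if dataset.extras:
        frames = []
        for caller, df in dataset.extras.items():
            block = pd.concat([key, df], axis=1)
            block.insert(4, "caller", caller)
            frames.append(block[np.isfinite(df["quality"].to_numpy(dtype=float))])
        paths["extras"] = out_dir / "extras.tsv"
        pd.concat(frames).to_csv(paths["extras"], sep="\t", index=False, na_rep=".")
    return paths
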