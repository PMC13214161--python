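"""Synthetic multi-site TSPO PET cohort generator.

Emulates the structure of a multi-tracer, multi-batch clinical TSPO PET
study so every pipeline stage can be exercised without real data. Regional
kinetics follow a one-tissue reversible model whose washout is slowed by
effective target expression:

    C_t(t) = K1 * (exp(-k2_eff t) conv C_p)(t),
    k2_eff = k2_base / (1 + f_s * E_r)

with regional influx K1_r (delivery), regional expression E_r shared
between left/right homologues, and a specific-binding fraction f_s scaled
by binder genotype and suppressed by pharmacological occupancy
(f_s -> f_s * (1 - o)) and by dose saturation. The input function is a
gamma-variate scaled with injected dose. Curves are generated at the frame
mid-times (with a virtual t=0 zero sample) using an exact piecewise-linear
convolution, so in the irreversible limit (k2_eff = 0) the tissue curve is
the trapezoid-cumulated input times K1 and the influx estimator's closed
loop is exact.

A separate edge-level generator plants additive covariate, batch, and
disease effects directly on similarity edges with known ground truth, for
testing the harmonization and classification stages.

All randomness flows from the master seed through named
``numpy.random.SeedSequence`` substreams, in this fixed order: kinetic
template, covariates, session jitter, frame noise. Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, load_atlas
from .io import RegionalTacSet, SubjectRecord
from .network import edge_index_pairs

__all__ = [
    "FrameSchedule", "BatchSpec", "DiseaseSpec", "CohortBlock", "SimConfig",
    "SimTruth", "SimCohort", "kinetic_template", "simulate_input_function",
    "simulate_tissue_tac", "simulate_cohort", "write_cohort",
    "simulate_edge_cohort", "PBR28_SCHEDULE", "SHORT_SCHEDULE",
]

# (frame count, frame duration in minutes)
PBR28_SCHEDULE = ((8, 0.25), (3, 1.0), (5, 2.0), (5, 5.0), (5, 10.0))  # 90 min
SHORT_SCHEDULE = ((6, 0.25), (4, 1.0), (4, 3.0), (4, 5.0), (3, 10.0))  # ~67 min


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing derived from (count, duration) blocks."""

    blocks: tuple

    @property
    def frame_start(self) -> np.ndarray:
        durs = self.frame_durations
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    @property
    def frame_end(self) -> np.ndarray:
        return np.cumsum(self.frame_durations)

    @property
    def frame_durations(self) -> np.ndarray:
        out = []
        for n, d in self.blocks:
            if n < 1 or d <= 0:
                raise ValueError("invalid frame schedule block")
            out += [float(d)] * int(n)
        return np.asarray(out)

    @property
    def mid_times(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2.0


@dataclass(frozen=True)
class BatchSpec:
    """One acquisition batch: site/scanner/protocol combination."""

    name: str
    tracer: str = "PBR28"
    schedule: tuple = PBR28_SCHEDULE
    scale: float = 1.0          # global multiplicative activity bias
    noise_level: float = 0.1    # frame noise coefficient
    genotyped: bool = True      # False for first-generation-tracer batches


@dataclass(frozen=True)
class DiseaseSpec:
    """Regional perturbation of target expression for one disease group."""

    group: str
    target_rois: tuple          # region names
    expression_multiplier: float = 1.5


@dataclass(frozen=True)
class CohortBlock:
    """n subjects of one group scanned in one batch, with a session mode
    (``single``, ``test_retest`` or ``blocking``)."""

    batch: str
    group: str
    n: int
    sessions: str = "single"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a realistic second-generation-tracer study: ~10%
    between-subject regional kinetic variability, moderate frame noise,
    males ~10% lower spatial kinetic contrast (yielding the observed higher
    male similarity), mixed-affinity binders with 60% of the high-affinity
    specific-binding fraction, similarity decreasing with age via greater
    expression heterogeneity, and mild dose-saturation flattening.
    """

    atlas_name: str = "reduced"
    batches: tuple = (BatchSpec("SITE1"),)
    cohort: tuple = (CohortBlock("SITE1", "HC", 10),)
    diseases: tuple = ()
    # kinetic template
    k1_range: tuple = (0.08, 0.14)      # per-minute influx across regions
    expression_range: tuple = (0.5, 3.0)
    k2_base: float = 0.08               # per-minute intrinsic washout
    fs_base: float = 1.0
    # covariate effects
    male_k1_multiplier: float = 0.9
    genotype_fs: tuple = (("HAB", 1.0), ("MAB", 0.6))
    mab_fraction: float = 0.4
    age_range: tuple = (20.0, 70.0)
    age_heterogeneity: float = 0.5      # expression-spread gain per 40 years
    dose_range: tuple = (150.0, 500.0)  # MBq
    weight_range: tuple = (55.0, 95.0)  # kg
    dose_saturation: float = 0.2        # f_s reduction at the max dose/weight
    # variability
    subject_sd: float = 0.10            # between-subject log-normal kinetics
    session_sd: float = 0.02            # test-retest session jitter
    occupancy: float = 0.9              # blocking occupancy
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth sufficient to recompute every noiseless TAC."""

    roi_names: tuple
    template_k1: np.ndarray
    template_expression: np.ndarray
    scans: dict = field(default_factory=dict)   # scan_id -> per-scan truth
    disease_targets: dict = field(default_factory=dict)  # group -> roi indices
    batch_scales: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class SimCohort:
    scans: list
    records: list
    truth: SimTruth
    atlas: RoiAtlas


def kinetic_template(atlas: RoiAtlas, config: SimConfig, seed_seq) -> tuple:
    """Draw per-region baseline influx K1_r and expression E_r, shared
    between homologues (paired regions get identical values)."""
    rng = np.random.default_rng(seed_seq)
    k1 = np.empty(atlas.n_roi)
    expr = np.empty(atlas.n_roi)
    done = np.zeros(atlas.n_roi, dtype=bool)
    for i in range(atlas.n_roi):
        if done[i]:
            continue
        k1_i = rng.uniform(*config.k1_range)
        e_i = rng.uniform(*config.expression_range)
        k1[i], expr[i] = k1_i, e_i
        done[i] = True
        j = atlas.homolog_map.get(i)
        if j is not None:
            k1[j], expr[j] = k1_i, e_i
            done[j] = True
    return k1, expr


def simulate_input_function(dose: float, times, *, alpha: float = 2.0,
                            tau: float = 0.75, amplitude_per_mbq: float = 0.12,
                            seed=None) -> np.ndarray:
    """Gamma-variate input function C_p(t) = A t^alpha exp(-t/tau), peaking
    at t = alpha*tau, with A proportional to injected dose (an optional
    seeded +/-10% amplitude jitter emulates delivery variability)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(times < 0):
        raise ValueError("invalid time grid")
    peak = (alpha * tau) ** alpha * np.exp(-alpha)
    amp = amplitude_per_mbq * dose / peak
    if seed is not None:
        amp *= np.exp(np.random.default_rng(seed).normal(0.0, 0.1))
    with np.errstate(invalid="ignore"):
        curve = amp * np.power(times, alpha) * np.exp(-times / tau)
    curve[times == 0] = 0.0
    return curve


def simulate_tissue_tac(times, input_curve, k1: float, k2_eff: float) -> np.ndarray:
    """One-tissue response K1 * (exp(-k2_eff t) conv C_p) at the given time
    points.

    The input is treated as piecewise-linear from a virtual (0, 0) sample;
    each segment's convolution integral is evaluated in closed form, so the
    k2_eff = 0 limit reduces exactly to K1 times the trapezoid-cumulated
    input.
    """
    if k1 < 0 or k2_eff < 0:
        raise ValueError("rate constants must be non-negative")
    t = np.concatenate([[0.0], np.asarray(times, dtype=float)])
    cp = np.concatenate([[0.0], np.asarray(input_curve, dtype=float)])
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing and > 0")
    y = np.zeros_like(t)
    for n in range(len(t) - 1):
        h = t[n + 1] - t[n]
        a = cp[n]
        b = (cp[n + 1] - cp[n]) / h
        x = k2_eff * h
        if x < 1e-8:
            seg = a * h + b * h * h / 2.0
            decay = 1.0 - x
        else:
            em = np.exp(-x)
            seg = a * (1.0 - em) / k2_eff + b * (h / k2_eff - (1.0 - em) / k2_eff ** 2)
            decay = em
        y[n + 1] = y[n] * decay + seg
    return k1 * y[1:]


def _effective_fs(config: SimConfig, genotype: str, occupancy: float,
                  dose_over_weight: float) -> float:
    geno_map = dict(config.genotype_fs)
    g = geno_map.get(genotype, 1.0)
    dw_max = config.dose_range[1] / config.weight_range[0]
    sat = 1.0 - config.dose_saturation * (dose_over_weight / dw_max)
    return max(config.fs_base * g * (1.0 - occupancy) * max(sat, 0.0), 0.0)


def _scan_kinetics(config, template_k1, template_expr, subj_jitter_k1,
                   subj_jitter_e, sess_jitter, record, occupancy, disease_idx,
                   disease_mult):
    """Per-scan regional K1 and k2_eff from template, subject effects and
    covariates."""
    k1 = template_k1 * np.exp(subj_jitter_k1 + sess_jitter)
    if record.sex == "M":
        # a global scale < 1 compresses spatial contrast, raising similarity
        k1 = k1 * config.male_k1_multiplier
    expr = template_expr * np.exp(subj_jitter_e)
    if disease_idx is not None:
        expr = expr.copy()
        expr[np.asarray(disease_idx, dtype=int)] *= disease_mult
    # age widens expression heterogeneity around its mean
    age_gain = 1.0 + config.age_heterogeneity * (record.age - 40.0) / 40.0
    expr = expr.mean() + max(age_gain, 0.1) * (expr - expr.mean())
    expr = np.clip(expr, 0.05, None)
    fs = _effective_fs(config, record.genotype, occupancy,
                       record.dose_over_weight)
    k2_eff = config.k2_base / (1.0 + fs * expr)
    return k1, expr, k2_eff, fs


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full synthetic cohort: scans, manifest records and
    ground truth.

    Each cohort block contributes ``n`` subjects; ``test_retest`` blocks
    emit two sessions per subject (tags ``test``/``retest``) and
    ``blocking`` blocks a ``baseline`` and a ``block`` scan (the latter at
    the configured occupancy).
    """
    atlas = load_atlas(config.atlas_name)
    batch_map = {b.name: b for b in config.batches}
    for blk in config.cohort:
        if blk.batch not in batch_map:
            raise ValueError(f"cohort block references unknown batch {blk.batch!r}")
    disease_map = {d.group: d for d in config.diseases}
    groups_present = {blk.group for blk in config.cohort}
    for g in disease_map:
        if g not in groups_present:
            raise ValueError(f"disease spec for absent group {g!r}")

    ss = np.random.SeedSequence(config.seed)
    ss_template, ss_cov, ss_sess, ss_noise = ss.spawn(4)
    template_k1, template_expr = kinetic_template(atlas, config, ss_template)
    rng_cov = np.random.default_rng(ss_cov)
    rng_sess = np.random.default_rng(ss_sess)
    rng_noise = np.random.default_rng(ss_noise)

    truth = SimTruth(roi_names=atlas.roi_names, template_k1=template_k1,
                     template_expression=template_expr, seed=config.seed,
                     batch_scales={b.name: b.scale for b in config.batches})
    name_to_idx = {n: i for i, n in enumerate(atlas.roi_names)}
    for d in disease_map.values():
        missing = [r for r in d.target_rois if r not in name_to_idx]
        if missing:
            raise ValueError(f"disease target region(s) not in atlas: {missing}")
        truth.disease_targets[d.group] = tuple(name_to_idx[r]
                                               for r in d.target_rois)

    scans, records = [], []
    subj_counter = 0
    for blk in config.cohort:
        batch = batch_map[blk.batch]
        sched = FrameSchedule(batch.schedule)
        mids = sched.mid_times
        for _ in range(blk.n):
            subj_counter += 1
            subject_id = f"sub{subj_counter:04d}"
            sex = "M" if rng_cov.random() < 0.5 else "F"
            age = rng_cov.uniform(*config.age_range)
            genotype = ("MAB" if rng_cov.random() < config.mab_fraction
                        else "HAB") if batch.genotyped else "NA"
            dose = rng_cov.uniform(*config.dose_range)
            weight = rng_cov.uniform(*config.weight_range)
            # subject effects shared between homologues
            jit_k1 = np.empty(atlas.n_roi)
            jit_e = np.empty(atlas.n_roi)
            done = np.zeros(atlas.n_roi, dtype=bool)
            for i in range(atlas.n_roi):
                if done[i]:
                    continue
                a = rng_cov.normal(0.0, config.subject_sd)
                b = rng_cov.normal(0.0, config.subject_sd)
                jit_k1[i], jit_e[i] = a, b
                done[i] = True
                j = atlas.homolog_map.get(i)
                if j is not None:
                    jit_k1[j], jit_e[j] = a, b
                    done[j] = True

            if blk.sessions == "single":
                session_specs = [("single", 0.0)]
            elif blk.sessions == "test_retest":
                session_specs = [("test", 0.0), ("retest", 0.0)]
            elif blk.sessions == "blocking":
                session_specs = [("baseline", 0.0), ("block", config.occupancy)]
            else:
                raise ValueError(f"unknown session mode {blk.sessions!r}")

            dspec = disease_map.get(blk.group)
            for session, occ in session_specs:
                scan_id = f"{subject_id}_{session}" if session != "single" \
                    else subject_id
                sess_jit = (rng_sess.normal(0.0, config.session_sd, atlas.n_roi)
                            if session == "retest" else np.zeros(atlas.n_roi))
                record = SubjectRecord(
                    scan_id=scan_id, subject_id=subject_id,
                    tracer=batch.tracer, batch=batch.name, group=blk.group,
                    sex=sex, age=age, genotype=genotype, injected_dose=dose,
                    body_weight=weight, session=session,
                    tac_file=f"{scan_id}.csv")
                k1, expr, k2_eff, fs = _scan_kinetics(
                    config, template_k1, template_expr, jit_k1, jit_e,
                    sess_jit, record, occ,
                    truth.disease_targets.get(blk.group),
                    dspec.expression_multiplier if dspec else 1.0)
                cp = simulate_input_function(dose, mids) * batch.scale
                activity = np.empty((mids.size, atlas.n_roi))
                for r in range(atlas.n_roi):
                    activity[:, r] = simulate_tissue_tac(
                        mids, cp, k1[r], k2_eff[r])
                if batch.noise_level > 0:
                    sd = batch.noise_level * np.sqrt(
                        np.clip(activity, 1e-12, None)
                        / sched.frame_durations[:, None])
                    activity = activity + rng_noise.normal(0.0, 1.0,
                                                           activity.shape) * sd
                    activity = np.clip(activity, 0.0, None)
                scans.append(RegionalTacSet(
                    scan_id=scan_id, subject_id=subject_id,
                    tracer=batch.tracer, batch=batch.name,
                    frame_start=sched.frame_start, frame_end=sched.frame_end,
                    activity=activity, input_curve=cp, injected_dose=dose,
                    body_weight=weight, roi_names=atlas.roi_names))
                records.append(record)
                truth.scans[scan_id] = {
                    "k1": k1.tolist(), "k2_eff": k2_eff.tolist(),
                    "expression": expr.tolist(), "fs": fs,
                    "occupancy": occ, "sex": sex, "age": age,
                    "genotype": genotype, "dose": dose, "weight": weight,
                    "batch": batch.name, "group": blk.group,
                    "session": session}
    return SimCohort(scans=scans, records=records, truth=truth, atlas=atlas)


def write_cohort(cohort: SimCohort, out_dir) -> None:
    """Write a simulated cohort as TAC CSVs, a manifest CSV and a
    ground-truth JSON (fixed float formatting; identical seeds give
    identical bytes)."""
    out_dir = Path(out_dir)
    tac_dir = out_dir / "tacs"
    tac_dir.mkdir(parents=True, exist_ok=True)
    for scan in cohort.scans:
        df = pd.DataFrame({"frame_start": scan.frame_start,
                           "frame_end": scan.frame_end,
                           "input": scan.input_curve})
        for i, name in enumerate(cohort.atlas.roi_names):
            df[name] = scan.activity[:, i]
        df.to_csv(tac_dir / f"{scan.scan_id}.csv", index=False,
                  float_format="%.10g")
    rows = []
    for r in cohort.records:
        rows.append({"scan_id": r.scan_id, "subject_id": r.subject_id,
                     "tracer": r.tracer, "batch": r.batch, "group": r.group,
                     "sex": r.sex, "age": f"{r.age:.10g}",
                     "genotype": r.genotype,
                     "injected_dose": f"{r.injected_dose:.10g}",
                     "body_weight": f"{r.body_weight:.10g}",
                     "session": r.session, "tac_file": r.tac_file})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    truth = cohort.truth
    payload = {
        "seed": truth.seed,
        "roi_names": list(truth.roi_names),
        "template_k1": truth.template_k1.tolist(),
        "template_expression": truth.template_expression.tolist(),
        "batch_scales": truth.batch_scales,
        "disease_targets": {k: list(v) for k, v in truth.disease_targets.items()},
        "scans": truth.scans,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_edge_cohort(*, n_per_group, atlas: RoiAtlas | int = 20,
                         batches=("SITE1",), batch_offsets=None,
                         sex_effect: float = 0.0, age_effect: float = 0.0,
                         genotype_effect: float = 0.0, dw_effect: float = 0.0,
                         disease_effects=None, group_signature_sd: float = 0.0,
                         noise_sd: float = 0.02, seed: int = 0):
    """Edge-level cohort with additive, known covariate / batch / disease
    effects.

    Generates ``edges[scan, edge] = base[edge] + covariate shifts + batch
    offset + disease shift on edges incident to the target regions +
    per-group signature + iid noise``, along with a covariate frame and the
    injected ground truth. Continuous covariates enter centered (age at 40
    years, dose-over-weight at 4 MBq/kg) so the offsets are directly the
    fitted coefficients.

    Parameters
    ----------
    n_per_group : dict
        Group name -> number of scans (e.g. ``{"HC": 30, "MS": 20}``).
    disease_effects : dict, optional
        Group -> ``(target_roi_indices, additive_edge_shift)`` applied to
        all edges incident to the targets.
    batch_offsets : dict, optional
        Batch name -> additive scalar shift on every edge (reference batch
        should be 0).
    """
    n_roi = atlas.n_roi if isinstance(atlas, RoiAtlas) else int(atlas)
    n_edges = n_roi * (n_roi - 1) // 2
    pairs = edge_index_pairs(n_roi)
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, n_edges)
    batches = tuple(batches)
    batch_offsets = dict(batch_offsets or {b: 0.0 for b in batches})
    disease_effects = dict(disease_effects or {})
    signatures = {}

    rows, data = [], []
    scan_counter = 0
    for group, n in n_per_group.items():
        if group_signature_sd > 0:
            signatures[group] = rng.normal(0.0, group_signature_sd, n_edges)
        for i in range(n):
            scan_counter += 1
            batch = batches[scan_counter % len(batches)]
            sex = "M" if rng.random() < 0.5 else "F"
            age = rng.uniform(20, 70)
            genotype = "MAB" if rng.random() < 0.4 else "HAB"
            dw = rng.uniform(2.0, 6.0)
            y = base.copy()
            y += batch_offsets.get(batch, 0.0)
            y += sex_effect * (sex == "M")
            y += age_effect * (age - 40.0)
            y += genotype_effect * (genotype == "MAB")
            y += dw_effect * (dw - 4.0)
            if group in disease_effects:
                targets, delta = disease_effects[group]
                incident = np.isin(pairs[:, 0], targets) | \
                    np.isin(pairs[:, 1], targets)
                y[incident] += delta
            if group in signatures:
                y += signatures[group]
            y += rng.normal(0.0, noise_sd, n_edges)
            rows.append({"scan_id": f"edge{scan_counter:04d}",
                         "subject_id": f"edge{scan_counter:04d}",
                         "group": group, "batch": batch, "sex": sex,
                         "age": age, "genotype": genotype,
                         "dose_over_weight": dw})
            data.append(y)
    covariates = pd.DataFrame(rows).set_index("scan_id")
    edges = np.vstack(data)
    incident_edges = {
        g: np.flatnonzero(np.isin(pairs[:, 0], t) | np.isin(pairs[:, 1], t))
        for g, (t, _) in disease_effects.items()}
    truth = {"base": base, "batch_offsets": batch_offsets,
             "sex_effect": sex_effect, "age_effect": age_effect,
             "genotype_effect": genotype_effect, "dw_effect": dw_effect,
             "disease_effects": disease_effects,
             "disease_incident_edges": incident_edges,
             "group_signatures": signatures, "noise_sd": noise_sd,
             "seed": seed}
    return edges, covariates, truth
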