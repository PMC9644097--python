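"""Synthetic longitudinal EV small-RNA cohort generator.

Emulates a neoadjuvant-chemotherapy (NAC) breast-cancer cohort with healthy
controls: per-subject serial samples, negative-binomial feature counts with a
realistic biotype composition, nanoparticle-tracking (NTA) particle
concentrations with treatment dynamics, and "planted" marker RNAs carried by
a subset of subjects, so the downstream selection logic can be tested against
a known ground truth.

Counts are generated at feature level by default (mean = library size x
composition share, NB variance mu + phi*mu^2).  An optional read-level mode
lays the features out on a synthetic chromosome and emits BED6 alignment
intervals so the hierarchical counting stage can be exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import CountMatrix

#: Canonical biotype vocabulary, in the read-assignment priority order.
BIOTYPES = [
    "miRNA", "tRNA", "rRNA", "mRNA", "pseudogene",
    "snRNA", "snoRNA", "piRNA", "lncRNA", "miscRNA",
]

#: Mean biotype composition of plasma-EV small-RNA reads.  The five named
#: classes follow the observed cohort means (lncRNA 26%, mRNA 25%, piRNA 18%,
#: miRNA 17%, tRNA-derived fragments 4%); the residual 10% is split evenly
#: over the minor classes.
DEFAULT_PROPORTIONS = {
    "lncRNA": 0.26, "mRNA": 0.25, "piRNA": 0.18, "miRNA": 0.17, "tRNA": 0.04,
    "rRNA": 0.02, "pseudogene": 0.02, "snRNA": 0.02, "snoRNA": 0.02,
    "miscRNA": 0.02,
}

DEFAULT_FEATURES_PER_BIOTYPE = {
    "lncRNA": 520, "mRNA": 500, "piRNA": 360, "miRNA": 340, "tRNA": 80,
    "rRNA": 40, "pseudogene": 40, "snRNA": 40, "snoRNA": 40, "miscRNA": 40,
}

#: Serial blood-draw timepoints for breast-cancer subjects: diagnosis, end of
#: chemotherapy, and 7 days / 6 months / 12 months after surgery.  Healthy
#: controls have the single pseudo-timepoint "HC".
TIMEPOINTS = ["Dg", "NAC", "PostOp7d", "PostOp6m", "PostOp12m"]
HC_TIMEPOINT = "HC"

#: Typical feature lengths (nt) used by the read-level mode.
_FEATURE_LENGTHS = {
    "miRNA": 22, "tRNA": 75, "rRNA": 120, "mRNA": 400, "pseudogene": 300,
    "snRNA": 150, "snoRNA": 100, "piRNA": 30, "lncRNA": 500, "miscRNA": 200,
}

#: Clinical-covariate marginal frequencies used to sample synthetic
#: characteristics for breast-cancer subjects (cohort of 35: e.g. ER+ 23/35).
_CLINICAL_MARGINS = {
    "grade": (["2", "3"], [23 / 35, 12 / 35]),
    "ER": (["pos", "neg"], [23 / 35, 12 / 35]),
    "PR": (["pos", "neg"], [17 / 35, 18 / 35]),
    "HER2": (["0", "1", "2", "3"], [6 / 35, 14 / 35, 4 / 35, 11 / 35]),
    "TNBC": (["yes", "no"], [8 / 35, 27 / 35]),
    "Ecadherin": (["pos", "neg"], [24 / 35, 11 / 35]),
    "Ki67": (["<=14%", ">14%"], [6 / 35, 29 / 35]),
    "Tstage": (["T1", "T2", "T3", "T4"], [1 / 35, 14 / 35, 18 / 35, 2 / 35]),
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class PlantedMarker:
    """A ground-truth marker RNA planted into the synthetic cohort.

    The marker is zero-inflated: non-carrier subjects have exactly zero
    counts; carrier subjects express it at ``2**expression_log2fc`` CPM at
    their active timepoints.  Carrier groups are drawn from response
    (R / NR) and 18-month progression (P / NP) strata.  With
    ``hc_detectable=False`` the marker is absent from every healthy-control
    sample by construction; otherwise a fraction ``hc_fraction`` of controls
    express it at the carrier level.
    """

    feature_id: str
    biotype: str
    carrier_groups: tuple = ("NR",)
    carrier_fraction: float = 0.3
    active_timepoints: tuple = ("Dg", "NAC")
    expression_log2fc: float = 8.0
    hc_detectable: bool = False
    hc_fraction: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ConfigurationError(
                f"carrier_fraction {self.carrier_fraction} outside [0, 1]"
            )
        if not np.isfinite(self.expression_log2fc):
            raise ConfigurationError("expression_log2fc must be finite")
        if self.biotype not in BIOTYPES:
            raise ConfigurationError(f"unknown biotype {self.biotype!r}")
        bad = set(self.carrier_groups) - {"R", "NR", "P", "NP"}
        if bad:
            raise ConfigurationError(f"unknown carrier groups {sorted(bad)}")
        bad_tp = set(self.active_timepoints) - set(TIMEPOINTS)
        if bad_tp:
            raise ConfigurationError(f"unknown timepoints {sorted(bad_tp)}")


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort.

    Defaults reproduce the study conditions: 30 healthy controls, 32 patients
    (12 responders, 20 non-responders), ~2.4 M mapped reads per library, the
    observed mean biotype composition, NB dispersion 0.3, and NTA particle
    concentrations in the observed 1.71e9 - 7.92e11 per-mL range with a
    NAC-driven rise that resolves by six months after surgery.
    """

    n_hc: int = 30
    n_responders: int = 12
    n_nonresponders: int = 20
    timepoints: tuple = tuple(TIMEPOINTS)
    n_features_per_biotype: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_BIOTYPE))
    biotype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    library_size_mean: float = 2.4e6
    library_size_cv: float = 0.25
    dispersion: float = 0.3
    particle_conc_hc_log10_mean: float = 10.2
    particle_conc_hc_log10_sd: float = 0.35
    particle_fold_dg_nr: float = 2.5
    particle_fold_dg_r: float = 1.4
    particle_fold_nac: float = 4.0
    particle_bounds: tuple = (1.71e9, 7.92e11)
    p_progression: float = 11 / 35
    planted_markers: list = field(default_factory=list)
    planted_nac_induced: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hc", "n_responders", "n_nonresponders"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        props = self.biotype_proportions
        vals = np.array(list(props.values()), dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "biotype_proportions must be nonnegative and sum to 1")
        unknown = set(props) - set(BIOTYPES)
        if unknown:
            raise ConfigurationError(f"unknown biotypes {sorted(unknown)}")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be > 0")
        for m in list(self.planted_markers) + list(self.planted_nac_induced):
            m.validate()

    def all_markers(self) -> list:
        return list(self.planted_markers) + list(self.planted_nac_induced)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        for key in ("planted_markers", "planted_nac_induced"):
            d[key] = [asdict(m) for m in getattr(self, key)]
        return d


@dataclass
class CohortDataset:
    """Bundle returned by :func:`simulate_cohort`."""

    samples: pd.DataFrame         # one row per sequenced sample
    counts: CountMatrix           # all samples in one matrix
    particles: pd.DataFrame       # NTA measurements, one row per sample
    config: SimulationConfig
    features: pd.DataFrame | None = None   # read-level annotation, if built

    def sample_ids(self, group=None, timepoint=None) -> list:
        s = self.samples
        mask = pd.Series(True, index=s.index)
        if group is not None:
            groups = [group] if isinstance(group, str) else list(group)
            mask &= s["group"].isin(groups)
        if timepoint is not None:
            mask &= s["timepoint"] == timepoint
        return s.loc[mask, "sample_id"].tolist()


def _make_subject_table(config: SimulationConfig, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Subjects with group, progression status and clinical covariates.

    Responder/non-responder labels follow the Miller-Payne dichotomy (grades
    1-3 non-responder, 4-5 responder); progression within 18 months is drawn
    independently of response.
    """
    rows = []
    for i in range(config.n_responders):
        rows.append({"subject_id": f"R{i + 1:02d}", "group": "R"})
    for i in range(config.n_nonresponders):
        rows.append({"subject_id": f"NR{i + 1:02d}", "group": "NR"})
    for i in range(config.n_hc):
        rows.append({"subject_id": f"HC{i + 1:02d}", "group": "HC"})
    subjects = pd.DataFrame(rows)

    bc = subjects["group"] != "HC"
    n_bc = int(bc.sum())
    prog = rng.random(n_bc) < config.p_progression
    subjects["progression_18m"] = "NA"
    subjects.loc[bc, "progression_18m"] = np.where(prog, "yes", "no")
    for cov, (levels, probs) in _CLINICAL_MARGINS.items():
        subjects[cov] = "NA"
        subjects.loc[bc, cov] = rng.choice(levels, size=n_bc, p=probs)
    return subjects


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float
             ) -> np.ndarray:
    """NB(mu, variance mu + phi*mu^2) via the gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _select_carriers(subjects: pd.DataFrame, marker: PlantedMarker,
                     rng: np.random.Generator) -> set:
    """Pick round(fraction * group size) carriers from each carrier stratum."""
    carriers: set = set()
    for g in marker.carrier_groups:
        if g in ("R", "NR"):
            pool = subjects.loc[subjects["group"] == g, "subject_id"]
        else:  # P / NP: progression strata over all BC subjects
            want = "yes" if g == "P" else "no"
            pool = subjects.loc[subjects["progression_18m"] == want,
                                "subject_id"]
        pool = pool.tolist()
        k = int(round(marker.carrier_fraction * len(pool)))
        if k > 0:
            carriers.update(rng.choice(pool, size=k, replace=False))
    return carriers


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a full synthetic cohort under ``config``.

    Deterministic for a fixed seed.  Per-sample counts are drawn feature-wise
    from NB(library_size x composition share, dispersion); planted markers
    appear only in their carrier subjects at their active timepoints, and
    markers with ``hc_detectable=False`` have exactly zero counts in every
    healthy-control sample.  The recorded library size is the realized column
    sum, so counts are conserved exactly.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_subj, rng_counts, rng_marker, rng_part = (
        np.random.default_rng(s) for s in ss.spawn(4))

    subjects = _make_subject_table(config, rng_subj)

    sample_rows = []
    for _, subj in subjects.iterrows():
        tps = [HC_TIMEPOINT] if subj["group"] == "HC" else list(config.timepoints)
        for tp in tps:
            row = subj.to_dict()
            row["timepoint"] = tp
            row["sample_id"] = f"{subj['subject_id']}_{tp}"
            sample_rows.append(row)
    samples = pd.DataFrame(sample_rows)

    # Fixed within-biotype relative abundances (Dirichlet), shared by all
    # samples so that features have stable expected shares.
    feat_ids, feat_bio, feat_share = [], [], []
    for bt in BIOTYPES:
        n = int(config.n_features_per_biotype.get(bt, 0))
        if n == 0:
            continue
        w = rng_counts.dirichlet(np.ones(n))
        share = config.biotype_proportions.get(bt, 0.0) * w
        feat_ids += [f"{bt}_{i + 1:04d}" for i in range(n)]
        feat_bio += [bt] * n
        feat_share.append(share)
    share = np.concatenate(feat_share) if feat_share else np.array([])

    markers = config.all_markers()
    marker_carriers = {m.feature_id: _select_carriers(subjects, m, rng_marker)
                       for m in markers}
    if markers:
        hc_ids = subjects.loc[subjects["group"] == "HC", "subject_id"].tolist()
        for m in markers:
            if m.hc_detectable and m.hc_fraction > 0 and hc_ids:
                k = int(round(m.hc_fraction * len(hc_ids)))
                marker_carriers[m.feature_id].update(
                    rng_marker.choice(hc_ids, size=k, replace=False))

    n_samples = len(samples)
    sigma = np.sqrt(np.log1p(config.library_size_cv ** 2))
    target_lib = np.exp(
        rng_counts.normal(np.log(config.library_size_mean) - sigma ** 2 / 2,
                          sigma, size=n_samples))

    cols = {}
    for j, row in samples.iterrows():
        mu = target_lib[j] * share
        col = _nb_draw(rng_counts, mu, config.dispersion)
        mcounts = np.zeros(len(markers), dtype=np.int64)
        for k, m in enumerate(markers):
            active = (row["timepoint"] in m.active_timepoints
                      or (row["group"] == "HC" and m.hc_detectable))
            if active and row["subject_id"] in marker_carriers[m.feature_id]:
                mu_m = target_lib[j] / 1e6 * 2.0 ** m.expression_log2fc
                mcounts[k] = _nb_draw(rng_counts, np.array([mu_m]),
                                      config.dispersion)[0]
            if row["group"] == "HC" and not m.hc_detectable:
                mcounts[k] = 0
        cols[row["sample_id"]] = np.concatenate([col, mcounts])

    all_ids = feat_ids + [m.feature_id for m in markers]
    all_bio = feat_bio + [m.biotype for m in markers]
    counts_df = pd.DataFrame(cols, index=pd.Index(all_ids, name="feature_id"))
    cm = CountMatrix(counts_df,
                     pd.Series(all_bio, index=counts_df.index, name="biotype"))
    samples = samples.set_index("sample_id", drop=False)
    samples["library_size"] = cm.library_size

    particles = simulate_particle_concentrations(config, samples, rng_part)
    return CohortDataset(samples=samples.reset_index(drop=True), counts=cm,
                         particles=particles, config=config)


def simulate_particle_concentrations(config: SimulationConfig,
                                     samples: pd.DataFrame,
                                     rng: np.random.Generator | None = None
                                     ) -> pd.DataFrame:
    """NTA particle concentrations per sample (particles/mL plasma).

    log10 concentrations are Gaussian per group/timepoint.  Pre-treatment
    cancer samples sit above the healthy baseline (non-responders more so);
    concentrations rise multiplicatively from diagnosis to the end of NAC,
    stay high 7 days after surgery, and return to the healthy baseline by 6
    and 12 months.  Values are clipped into the configured bounds.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(4)[3])
    base = config.particle_conc_hc_log10_mean
    sd = config.particle_conc_hc_log10_sd
    log_nac = np.log10(config.particle_fold_nac)

    shifts = {("HC", HC_TIMEPOINT): 0.0}
    for g, dg_fold in (("R", config.particle_fold_dg_r),
                       ("NR", config.particle_fold_dg_nr)):
        dg = np.log10(dg_fold)
        shifts[(g, "Dg")] = dg
        shifts[(g, "NAC")] = dg + log_nac
        shifts[(g, "PostOp7d")] = dg + log_nac
        shifts[(g, "PostOp6m")] = 0.0
        shifts[(g, "PostOp12m")] = 0.0

    lo, hi = config.particle_bounds
    rows = []
    for _, row in samples.iterrows():
        mu = base + shifts.get((row["group"], row["timepoint"]), 0.0)
        conc = 10.0 ** rng.normal(mu, sd)
        rows.append({
            "sample_id": row["sample_id"],
            "concentration": float(np.clip(conc, lo, hi)),
            "mode_size": float(np.clip(rng.normal(120.0, 15.0), 50.0, 300.0)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read-level mode


def build_annotation(config: SimulationConfig,
                     include_markers: bool = True) -> pd.DataFrame:
    """Lay every feature out on one synthetic chromosome, disjointly.

    Returns a BED-like frame (0-based half-open) with columns feature_id,
    biotype, chrom, start, end, strand.  Deterministic: feature order follows
    the count-matrix feature order, with a 50-nt gap between features.
    """
    rows = []
    pos = 0
    ids_bio = [(f"{bt}_{i + 1:04d}", bt)
               for bt in BIOTYPES
               for i in range(int(config.n_features_per_biotype.get(bt, 0)))]
    if include_markers:
        ids_bio += [(m.feature_id, m.biotype) for m in config.all_markers()]
    for fid, bt in ids_bio:
        length = _FEATURE_LENGTHS[bt]
        rows.append({"feature_id": fid, "biotype": bt, "chrom": "chrS",
                     "start": pos, "end": pos + length, "strand": "+"})
        pos += length + 50
    return pd.DataFrame(rows)


def emit_alignments(cm: CountMatrix, annotation: pd.DataFrame,
                    sample_id: str, seed: int,
                    min_read_len: int = 15, max_read_len: int = 35
                    ) -> pd.DataFrame:
    """Emit BED6 alignment intervals realizing one sample's counts.

    For each feature, draws ``count`` reads uniformly placed within the
    feature's annotated interval, with lengths in
    ``[min_read_len, min(max_read_len, feature length)]``.  Counting the
    emitted records with the hierarchical assigner recovers the generating
    counts exactly when the annotation is disjoint.
    """
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("feature_id")
    counts = cm.counts[sample_id]
    chroms, starts, ends, strands = [], [], [], []
    for fid, c in counts.items():
        if c == 0 or fid not in ann.index:
            continue
        f = ann.loc[fid]
        flen = int(f["end"] - f["start"])
        rlen = rng.integers(min_read_len, min(max_read_len, flen) + 1, size=c)
        off = (rng.random(c) * (flen - rlen + 1)).astype(int)
        chroms.append(np.full(c, f["chrom"], dtype=object))
        starts.append(int(f["start"]) + off)
        ends.append(int(f["start"]) + off + rlen)
        strands.append(np.full(c, f["strand"], dtype=object))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start", "end", "read_id",
                                     "score", "strand"])
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    strand = np.concatenate(strands)
    n = len(start)
    return pd.DataFrame({
        "chrom": chrom, "start": start, "end": end,
        "read_id": [f"{sample_id}_r{i + 1:07d}" for i in range(n)],
        "score": np.zeros(n, dtype=int), "strand": strand,
    })
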