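"""Synthetic blood small-RNA cohorts with planted structure.

The generator emulates a multi-group case/control study of noncanonical small
noncoding RNAs: per-parent cleavage hotspots define the fragment species (and
hence the multi-peaked read-length distributions), per-family abundances carry
planted group effects, age/sex covariate effects, a single latent factor that
also drives a block of co-expressed genes, and an optional per-miRNA
cohort-specific baseline shift.  Everything needed to score recovery — the
planted families, effect sizes, latent scores, gene sets — is returned as
:class:`SyntheticTruth`.

Counts are overdispersed: per-species Gamma intensities (shape = the
negative-binomial size parameter) are drawn and a single multinomial of the
library size is taken on the normalized intensities.  Marginally each species
behaves like a Gamma–Poisson (negative binomial) count, while per-sample
species counts sum *exactly* to the drawn library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .references import ParentalReference, write_reference_fasta  # noqa: F401

logger = logging.getLogger(__name__)

GROUPS = ("HC", "SC", "UC", "CD")

#: characteristic fragment lengths per parental class (nt) — tsRNAs peak at
#: 17/22, ysRNAs at 27/32, rsRNAs show a broader multi-peak profile
_CLASS_FRAGMENT_LENGTHS = {
    "GtRNA": (17, 22),
    "MtRNA": (17, 22),
    "YRNA": (27, 32),
    "rRNA": (15, 17, 23, 26, 33),
    "miRNA": (22,),
}


def log2_effect_for_sd_units(target_sd_units: float, dispersion: float) -> float:
    """Log2 group effect whose regression coefficient equals ``target_sd_units``
    residual standard deviations on the RPM scale.

    For a negative-binomial count with large mean and size ``r`` the
    within-group SD is proportional to the mean, so a multiplicative effect
    ``2**d`` makes the coefficient ``mu (2**d - 1)`` while the pooled residual
    SD over a balanced control/case design is
    ``mu sqrt((1 + 4**d) / (2 r))``.  The returned ``d`` solves
    ``(2**d - 1) sqrt(r) / sqrt((1 + 4**d)/2) = target``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if target_sd_units == 0:
        return 0.0
    from scipy.optimize import brentq

    def gap(d):
        return ((2.0 ** d - 1.0) * np.sqrt(dispersion)
                / np.sqrt((1.0 + 4.0 ** d) / 2.0)) - target_sd_units
    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise ValueError(
                f"target of {target_sd_units} residual SDs unreachable at "
                f"dispersion {dispersion}")
    return float(brentq(gap, 0.0, hi, xtol=1e-12))


@dataclass
class CohortConfig:
    """Design of one synthetic cohort.

    Defaults follow a four-group blood study: 30 healthy controls (HC),
    65 symptomatic controls (SC), 58 ulcerative colitis (UC) and 52 Crohn's
    disease (CD) samples.  ``effect_families`` plants multiplicative log2 group
    effects on named families; covariate and latent terms act on the log2
    abundance scale.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"HC": 30, "SC": 65, "UC": 58, "CD": 52})
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    #: list of (family_label, log2 effect, affected groups)
    effect_families: tuple = ()
    age_slope_sd: float = 0.003      # per-family SD of log2 slope per year
    sex_offset_sd: float = 0.10      # per-family SD of log2 male-vs-female offset
    family_abundance_sd: float = 2.0  # SD of per-family baseline log2 abundance
    latent_family_loadings: dict | None = None  # family_label -> log2 per latent unit
    latent_sd: float = 1.0
    latent_group_shift: dict = field(default_factory=dict)  # group -> latent mean shift
    mirna_cohort_shift_sd: float = 0.0  # SD of per-miRNA cohort log2 offset
    cohort_label: str = "cohortA"
    cleavage_hotspots: dict | None = None  # parent_id -> [(offset, length, weight)]
    dispersion: float = 10.0
    unannotatable_fraction: float = 0.02
    n_unannotatable_species: int = 20
    seed: int = 0

    def __post_init__(self):
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 2:
                raise ValueError(f"group {g}: size must be >= 2, got {n}")
        lo, hi = self.library_size_range
        if lo < 10_000 or hi < lo:
            raise ValueError("library sizes must be >= 10,000 and lo <= hi")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.unannotatable_fraction < 1:
            raise ValueError("unannotatable_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated cohort, for recovery scoring."""

    planted_up_families: set
    planted_effects: dict            # family_label -> log2 effect
    latent_scores: pd.Series         # per sample
    family_params: pd.DataFrame      # baseline, slopes, loadings, shifts per family
    library_sizes: pd.Series         # drawn library size per sample
    expected_family_rpm: pd.DataFrame  # families x samples, noise-free composition
    gene_coexpression_sets: dict = field(default_factory=dict)
    seeds_used: tuple = ()


@dataclass
class CohortData:
    """A generated cohort: species-level counts plus metadata and truth."""

    species: pd.DataFrame            # species_id -> sequence, parent, locus, class, family
    counts: pd.DataFrame             # species x samples, annotatable reads
    unannotatable: pd.DataFrame      # decoy species x samples
    unannotatable_sequences: pd.Series
    metadata: pd.DataFrame           # sample_id, group, age, sex, cohort
    truth: SyntheticTruth
    refs: list

    def family_counts(self) -> pd.DataFrame:
        """Integer read counts summed to family level (families x samples)."""
        return self.counts.groupby(self.species["family_label"]).sum()

    def retained_totals(self) -> pd.Series:
        """Per-sample total retained reads (annotatable + unannotatable)."""
        return self.counts.sum(axis=0) + self.unannotatable.sum(axis=0)

    def family_rpm(self, denominator_policy: str = "retained_total") -> pd.DataFrame:
        """Family-level RPM matrix under the chosen denominator policy."""
        fam = self.family_counts()
        if denominator_policy == "retained_total":
            denom = self.retained_totals()
        elif denominator_policy == "annotated_total":
            denom = self.counts.sum(axis=0)
        else:
            raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
        return fam * 1e6 / denom

    def class_totals(self, denominator_policy: str = "retained_total") -> pd.DataFrame:
        """tsRNA/rsRNA/ysRNA/miRNA total RPM per sample."""
        rpm = self.family_rpm(denominator_policy)
        return aggregate_class_totals(rpm)

    def to_reads(self) -> dict:
        """Collapsed reads per sample: ``{sample: [(read_id, seq, count), ...]}``."""
        out = {}
        seqs = self.species["sequence"]
        for s in self.counts.columns:
            reads = []
            col = self.counts[s]
            for i, (sp, c) in enumerate(col[col > 0].items()):
                reads.append((f"{s}_r{i:05d}", seqs[sp], int(c)))
            ucol = self.unannotatable[s]
            for j, (sp, c) in enumerate(ucol[ucol > 0].items()):
                reads.append((f"{s}_u{j:05d}", self.unannotatable_sequences[sp], int(c)))
            out[s] = reads
        return out


def class_of_family(label: str) -> str:
    """Map a family label to its summary class (tsRNA/rsRNA/ysRNA/miRNA)."""
    if label.startswith(("GtsRNA-", "MtsRNA-")):
        return "tsRNA"
    if label.startswith("rsRNA-"):
        return "rsRNA"
    if label.startswith("ysRNA-"):
        return "ysRNA"
    return "miRNA"


def aggregate_class_totals(family_rpm: pd.DataFrame) -> pd.DataFrame:
    classes = family_rpm.index.map(class_of_family)
    return family_rpm.groupby(classes).sum()


def default_hotspots(refs: list[ParentalReference],
                     rng: np.random.Generator) -> dict:
    """Cleavage hotspots per parent: 5'/3' fragments at the class-characteristic
    lengths, with Dirichlet-distributed weights."""
    hotspots = {}
    for r in refs:
        lengths = _CLASS_FRAGMENT_LENGTHS[r.rna_class]
        spots = []
        L = len(r.sequence)
        for i, frag_len in enumerate(lengths):
            if frag_len > L:
                continue
            if r.rna_class == "rRNA":
                # internal fragments spread across the parent
                offset = int(rng.integers(0, L - frag_len + 1))
            elif i % 2 == 0:
                offset = 0 if r.rna_class != "miRNA" else min(6, L - frag_len)
            else:
                offset = L - frag_len
            spots.append((offset, frag_len))
        w = rng.dirichlet(np.full(len(spots), 5.0))
        hotspots[r.parent_id] = [(o, l, float(wi)) for (o, l), wi in zip(spots, w)]
    return hotspots


def _validate_hotspots(hotspots: dict, refs_by_id: dict) -> None:
    for pid, spots in hotspots.items():
        if pid not in refs_by_id:
            raise ValueError(f"hotspots refer to unknown parent {pid!r}")
        L = len(refs_by_id[pid].sequence)
        wsum = 0.0
        for off, ln, w in spots:
            if off < 0 or ln <= 0 or off + ln > L:
                raise ValueError(
                    f"hotspot ({off}, {ln}) outside parental bounds of {pid} (length {L})")
            wsum += w
        if abs(wsum - 1.0) > 1e-8:
            raise ValueError(f"hotspot weights of {pid} sum to {wsum}, expected 1")


def generate_cohort(refs: list[ParentalReference],
                    config: CohortConfig,
                    template: "CohortData | None" = None) -> CohortData:
    """Draw a full synthetic cohort from the configured design.

    Per sample the expected species abundance is ``library_size x family weight
    x 2**(group effect + covariate terms + latent term + cohort shift)``;
    counts are Gamma–multinomial so they sum exactly to the drawn library size.
    A configurable fraction of unannotatable random reads is added on top.

    Passing a previously generated cohort as ``template`` reuses its cleavage
    hotspots and per-family parameters (baseline abundance, covariate slopes,
    latent loadings), so the new cohort shares the same underlying biology and
    differs only by sampling, design and the cohort-specific miRNA shift —
    the setting for cross-cohort divergence analyses.
    """
    if not refs:
        raise ValueError("refs must not be empty")
    rng = np.random.default_rng(config.seed)
    refs_by_id = {r.parent_id: r for r in refs}

    hotspots = config.cleavage_hotspots
    if hotspots is None:
        if template is not None:
            hotspots = {
                pid: [(int(r["start"]), int(r["length"]), float(r["hotspot_weight"]))
                      for _, r in grp.iterrows()]
                for pid, grp in template.species.groupby("parent_id")}
        else:
            hotspots = default_hotspots(refs, rng)
    _validate_hotspots(hotspots, refs_by_id)

    # --- species table -----------------------------------------------------
    rows = []
    for r in refs:
        for off, ln, w in hotspots.get(r.parent_id, []):
            rows.append({
                "species_id": f"{r.parent_id}:{off}-{off + ln}",
                "sequence": r.sequence[off:off + ln],
                "length": ln,
                "parent_id": r.parent_id,
                "start": off,
                "end": off + ln,
                "rna_class": r.rna_class,
                "family_label": r.family_label,
                "hotspot_weight": w,
            })
    species = pd.DataFrame(rows).set_index("species_id")
    families = species["family_label"].unique()

    # --- metadata ----------------------------------------------------------
    sample_rows = []
    for g in GROUPS:
        for i in range(config.group_sizes.get(g, 0)):
            sample_rows.append({
                "sample_id": f"{config.cohort_label}_{g}{i:03d}",
                "group": g,
                "age": float(rng.uniform(18, 80)),
                "sex": "M" if rng.integers(0, 2) else "F",
                "cohort": config.cohort_label,
            })
    metadata = pd.DataFrame(sample_rows).set_index("sample_id")
    samples = metadata.index
    n = len(samples)

    latent = rng.normal(0.0, config.latent_sd, size=n)
    latent += metadata["group"].map(
        lambda g: config.latent_group_shift.get(g, 0.0)).to_numpy()
    latent_scores = pd.Series(latent, index=samples, name="latent")

    # --- per-family parameters --------------------------------------------
    fam_class = species.drop_duplicates("family_label").set_index(
        "family_label")["rna_class"]
    fam_class = fam_class.reindex(families)
    m = len(families)
    loadings = pd.Series(0.0, index=families)
    if config.latent_family_loadings:
        for f, v in config.latent_family_loadings.items():
            if f not in loadings.index:
                raise ValueError(f"latent loading refers to unknown family {f!r}")
            loadings[f] = v
    cohort_shift = pd.Series(0.0, index=families)
    if config.mirna_cohort_shift_sd > 0:
        is_mir = (fam_class == "miRNA").to_numpy()
        cohort_shift[is_mir] = rng.normal(
            0.0, config.mirna_cohort_shift_sd, size=int(is_mir.sum()))
    if template is not None:
        shared = template.truth.family_params.reindex(families)
        if shared["baseline_log2"].isna().any():
            raise ValueError("template cohort does not cover the same families")
        family_params = pd.DataFrame({
            "rna_class": fam_class,
            "baseline_log2": shared["baseline_log2"],
            "age_slope_log2": shared["age_slope_log2"],
            "sex_offset_log2": shared["sex_offset_log2"],
            "latent_loading": shared["latent_loading"]
            if config.latent_family_loadings is None else loadings,
            "cohort_shift_log2": cohort_shift,
        }, index=pd.Index(families, name="family_label"))
    else:
        family_params = pd.DataFrame({
            "rna_class": fam_class,
            "baseline_log2": rng.normal(0.0, config.family_abundance_sd, size=m),
            "age_slope_log2": rng.normal(0.0, config.age_slope_sd, size=m),
            "sex_offset_log2": rng.normal(0.0, config.sex_offset_sd, size=m),
            "latent_loading": loadings,
            "cohort_shift_log2": cohort_shift,
        }, index=pd.Index(families, name="family_label"))

    effects = pd.DataFrame(0.0, index=families, columns=list(GROUPS))
    planted_effects, planted_up = {}, set()
    for fam, log2_effect, groups in config.effect_families:
        if fam not in effects.index:
            raise ValueError(f"effect_families refers to unknown family {fam!r}")
        for g in groups:
            effects.loc[fam, g] = log2_effect
        planted_effects[fam] = float(log2_effect)
        if log2_effect > 0:
            planted_up.add(fam)

    # --- per-sample expected composition ------------------------------------
    fp = family_params.loc[species["family_label"]]
    base = (fp["baseline_log2"].to_numpy()
            + np.log2(np.maximum(species["hotspot_weight"].to_numpy(), 1e-300)))
    age_c = metadata["age"].to_numpy() - 49.0
    sex01 = (metadata["sex"] == "M").to_numpy().astype(float)
    group_eff = effects.loc[species["family_label"],
                            metadata["group"]].to_numpy()  # species x samples
    log2_w = (base[:, None]
              + group_eff
              + fp["age_slope_log2"].to_numpy()[:, None] * age_c[None, :]
              + fp["sex_offset_log2"].to_numpy()[:, None] * sex01[None, :]
              + fp["latent_loading"].to_numpy()[:, None] * latent[None, :]
              + fp["cohort_shift_log2"].to_numpy()[:, None])
    w = np.exp2(log2_w - log2_w.max(axis=0, keepdims=True))
    p = w / w.sum(axis=0, keepdims=True)

    lib = rng.integers(config.library_size_range[0],
                       config.library_size_range[1] + 1, size=n)
    library_sizes = pd.Series(lib, index=samples, name="library_size")

    r = config.dispersion
    counts = np.empty((len(species), n), dtype=np.int64)
    for j in range(n):
        lam = rng.gamma(shape=r, scale=p[:, j] / r)
        counts[:, j] = rng.multinomial(lib[j], lam / lam.sum())
    counts_df = pd.DataFrame(counts, index=species.index, columns=samples)

    expected_species_rpm = pd.DataFrame(p * 1e6, index=species.index, columns=samples)
    expected_family_rpm = expected_species_rpm.groupby(
        species["family_label"]).sum()

    # --- unannotatable reads ------------------------------------------------
    k = config.n_unannotatable_species
    useqs, ucounts = [], np.zeros((k, n), dtype=np.int64)
    if config.unannotatable_fraction > 0 and k > 0:
        alphabet = np.array(list("ACGT"))
        while len(useqs) < k:
            ln = int(rng.integers(15, 46))
            seq = "".join(alphabet[rng.integers(0, 4, size=ln)])
            if any(seq in ref.sequence for ref in refs):
                continue
            useqs.append(seq)
        uprobs = rng.dirichlet(np.full(k, 2.0))
        for j in range(n):
            extra = int(round(config.unannotatable_fraction * lib[j]))
            ucounts[:, j] = rng.multinomial(extra, uprobs)
    else:
        useqs = [""] * 0
        ucounts = np.zeros((0, n), dtype=np.int64)
        k = 0
    u_index = pd.Index([f"decoy{i:03d}" for i in range(k)], name="species_id")
    unann = pd.DataFrame(ucounts, index=u_index, columns=samples)
    unann_seqs = pd.Series(useqs, index=u_index, name="sequence")

    truth = SyntheticTruth(
        planted_up_families=planted_up,
        planted_effects=planted_effects,
        latent_scores=latent_scores,
        family_params=family_params,
        library_sizes=library_sizes,
        expected_family_rpm=expected_family_rpm,
        seeds_used=(config.seed,),
    )
    return CohortData(species=species, counts=counts_df, unannotatable=unann,
                      unannotatable_sequences=unann_seqs, metadata=metadata,
                      truth=truth, refs=refs)


@dataclass
class GeneMatrixConfig:
    """Design of the coupled synthetic gene-expression matrix."""

    n_genes: int = 1000
    n_positive: int = 40
    n_negative: int = 60
    loading: float = 1.0         # intensity units per latent unit
    noise_sd: float = 1.0
    baseline_mean: float = 8.0   # log-scale array-intensity baseline
    baseline_sd: float = 1.0
    n_decoy_sets: int = 10
    decoy_set_size: int = 40
    seed: int = 0

    def __post_init__(self):
        biggest = max(self.n_positive, self.n_negative, self.decoy_set_size)
        if self.n_genes < biggest:
            raise ValueError(
                f"n_genes ({self.n_genes}) smaller than the largest requested "
                f"gene set ({biggest})")


def generate_gene_matrix(truth: SyntheticTruth,
                         config: GeneMatrixConfig) -> tuple[pd.DataFrame, dict]:
    """Gene expression coupled to the cohort's latent factor.

    Gene ``g``: ``baseline_g + loading_g x latent_score_s + noise``.  The
    positive-loading genes form gene set ``POS_PATH``, the negative-loading
    genes ``NEG_PATH``; random decoy sets are added.  Set membership is also
    recorded in ``truth.gene_coexpression_sets``.
    """
    rng = np.random.default_rng(config.seed)
    samples = truth.latent_scores.index
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    loadings = np.zeros(config.n_genes)
    loadings[: config.n_positive] = config.loading
    loadings[config.n_positive: config.n_positive + config.n_negative] = -config.loading
    rng.shuffle(loadings)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    z = truth.latent_scores.to_numpy()
    expr = (baseline[:, None] + loadings[:, None] * z[None, :]
            + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples))))
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)

    gene_arr = np.array(genes)
    sets = {
        "POS_PATH": list(gene_arr[loadings > 0]),
        "NEG_PATH": list(gene_arr[loadings < 0]),
    }
    for i in range(config.n_decoy_sets):
        sets[f"DECOY_{i:02d}"] = list(
            rng.choice(gene_arr, size=config.decoy_set_size, replace=False))
    truth.gene_coexpression_sets = {
        "positive": set(sets["POS_PATH"]),
        "negative": set(sets["NEG_PATH"]),
    }
    return expr_df, sets


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    """Write gene sets in GMT: name, description, tab-separated gene ids."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
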