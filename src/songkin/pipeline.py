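"""End-to-end analysis pipeline.

Runs the full chain — phrase features → PCA (one per phrase type ×
parameter set) → Euclidean distances → individual averaging →
normalization → relatedness → Mantel tests (population, per sex,
kin-category) → pDFA (individuality overall/per sex, group membership) —
from input files or from the synthetic generator, and writes long-format
CSV reports plus a JSON run manifest.  A fixed seed makes the whole run
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import META_COLUMNS, feature_table
from .mantel import kin_category_mantel, mantel_test, parent_offspring_design
from .matrix import SquareMatrix, normalize01
from .pca import individual_mean_distance, pca_kaiser, phrase_distance
from .pedigree import (FEMALE, MALE, GenotypeTable, Pedigree, default_loci,
                       simulate_genotypes, simulate_pedigree, study_pedigree)
from .phrase import read_phrases, write_phrases
from .relatedness import (allele_frequencies, compare_estimators,
                          relatedness_matrix, relatedness_to_distance)
from .pdfa import PDFAConfig, pdfa, pdfa_by_sex, pdfa_group
from .songsim import SongEffectConfig, simulate_phrases

__all__ = ["RunConfig", "PipelineError", "filter_individuals", "run_all"]

log = logging.getLogger(__name__)

KINDS = ("temporal", "frequency")


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either provide the four input CSV paths, or leave them unset to run on
    a synthetic dataset (the default seven-group study population).
    """

    # inputs (file mode); all-or-none
    phrase_csv: str | None = None
    contour_csv: str | None = None
    genotype_csv: str | None = None
    pedigree_csv: str | None = None
    # simulation mode
    pedigree_kind: str = "study"            # "study" | "random"
    n_groups: int = 7
    offspring_range: tuple[int, int] = (0, 2)
    song: SongEffectConfig = field(default_factory=SongEffectConfig)
    # analysis settings
    min_phrases: int = 4
    mantel_permutations: int = 9999
    kin_permutations: int = 9999
    pdfa_selections: int = 100
    pdfa_permutations: int = 1000
    pdfa_selections_null: int | None = None
    estimator: str = "dyadic_ml"
    grid_resolution: float = 0.01
    rotate: bool = False
    compare_estimators_n: int | None = None
    # stage toggles
    run_mantel: bool = True
    run_kin: bool = True
    run_pdfa: bool = True
    # bookkeeping
    out_dir: str = "songkin_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = (self.phrase_csv, self.contour_csv, self.genotype_csv,
                 self.pedigree_csv)
        given = [p is not None for p in paths]
        if any(given) and not all(given):
            raise ValueError("provide all four input paths or none")
        if self.min_phrases < 1:
            raise ValueError("min_phrases must be >= 1")
        if self.pedigree_kind not in ("study", "random"):
            raise ValueError(f"unknown pedigree_kind {self.pedigree_kind!r}")

    @property
    def simulate(self) -> bool:
        return self.phrase_csv is None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        song = raw.pop("song", None)
        kwargs = dict(raw)
        if song is not None:
            kwargs["song"] = SongEffectConfig(**song)
        if "offspring_range" in kwargs:
            kwargs["offspring_range"] = tuple(kwargs["offspring_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed, independent of stage execution order."""
    return np.random.SeedSequence(entropy=seed,
                                  spawn_key=(zlib.crc32(name.encode()),))


def filter_individuals(phrases, min_count: int = 4) -> dict[str, list]:
    """Keep, per phrase type independently, individuals with >= min_count
    phrases of that type.  The DP2 and DP3 cohorts may therefore differ."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    by_type: dict[str, list] = {}
    for p in phrases:
        by_type.setdefault(p.phrase_type, []).append(p)
    out: dict[str, list] = {}
    for ptype, plist in sorted(by_type.items()):
        counts: dict[str, int] = {}
        for p in plist:
            counts[p.individual] = counts.get(p.individual, 0) + 1
        keep = {ind for ind, c in counts.items() if c >= min_count}
        dropped = sorted(set(counts) - keep)
        if dropped:
            log.info("%s: dropping %d individual(s) below %d phrases: %s",
                     ptype, len(dropped), min_count, ", ".join(dropped))
        kept = [p for p in plist if p.individual in keep]
        if not kept:
            raise ValueError(f"{ptype}: no individuals reach "
                             f"{min_count} phrases")
        out[ptype] = kept
    return out


def _drop_constant(df: pd.DataFrame, feat_cols) -> list[str]:
    keep = []
    for c in feat_cols:
        if df[c].nunique() > 1:
            keep.append(c)
        else:
            log.info("dropping constant feature column %s", c)
    return keep


@dataclass
class RunResult:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    matrices: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name!r}: {err}") from err
        return wrapped
    return deco


@_stage("data")
def _load_data(cfg: RunConfig):
    if cfg.simulate:
        if cfg.pedigree_kind == "study":
            ped = study_pedigree()
        else:
            ped = simulate_pedigree(
                cfg.n_groups, cfg.offspring_range,
                np.random.default_rng(_stage_seed(cfg.seed, "pedigree")))
        loci = default_loci()
        gt = simulate_genotypes(
            ped, loci, np.random.default_rng(_stage_seed(cfg.seed, "genotypes")))
        phrases = simulate_phrases(
            ped, cfg.song, np.random.default_rng(_stage_seed(cfg.seed, "phrases")))
        return ped, gt, phrases
    for name, p in (("phrase", cfg.phrase_csv), ("contour", cfg.contour_csv),
                    ("pedigree", cfg.pedigree_csv)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    ped = Pedigree.from_csv(cfg.pedigree_csv)
    phrases = read_phrases(cfg.phrase_csv, cfg.contour_csv)
    return ped, None, phrases


@_stage("relatedness")
def _relatedness(cfg: RunConfig, gt: GenotypeTable | None):
    if gt is None:  # file mode: the genotype table is this stage's input
        if not Path(cfg.genotype_csv).exists():
            raise FileNotFoundError(
                f"genotype file not found: {cfg.genotype_csv}")
        gt = GenotypeTable.from_csv(cfg.genotype_csv)
    freqs = allele_frequencies(gt)
    rm = relatedness_matrix(gt, freqs, cfg.estimator, cfg.grid_resolution)
    gdist = relatedness_to_distance(rm)
    return freqs, rm, gdist


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all reports under ``cfg.out_dir``.

    Two runs with the same configuration and seed produce byte-identical
    outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = RunResult(out_dir=out)

    ped, gt, phrases = _load_data(cfg)
    if cfg.simulate:
        ped.to_csv(out / "pedigree.csv")
        gt.to_csv(out / "genotypes.csv")
        write_phrases(phrases, out / "phrases.csv", out / "contours.csv")

    cohorts = filter_individuals(phrases, cfg.min_phrases)
    sex_of = ped.sex_table()

    # --- acoustic side: one PCA + distance matrix per (type, kind) --------
    acoustic: dict[tuple[str, str], SquareMatrix] = {}
    cohort_inds: dict[str, list[str]] = {}
    for ptype, plist in cohorts.items():
        cohort_inds[ptype] = list(dict.fromkeys(p.individual for p in plist))
        for kind in KINDS:
            key = (ptype, kind)
            try:
                feats = feature_table(plist, kind)
                feat_cols = [c for c in feats.columns if c not in META_COLUMNS]
                feat_cols = _drop_constant(feats, feat_cols)
                feats.to_csv(out / f"features_{ptype}_{kind}.csv", index=False)
                pca = pca_kaiser(
                    feats[feat_cols].set_axis(feats["phrase_id"], axis=0),
                    rotate=cfg.rotate)
                pca.loadings.to_csv(out / f"pca_loadings_{ptype}_{kind}.csv",
                                    index_label="variable")
                pca.variance_table().to_csv(
                    out / f"pca_variance_{ptype}_{kind}.csv", index=False)
                d_phrase = phrase_distance(pca.scores)
                mapping = dict(zip(feats["phrase_id"].astype(str),
                                   feats["individual_id"].astype(str)))
                d_ind = normalize01(individual_mean_distance(d_phrase, mapping))
                d_ind.to_csv(out / f"dist_individual_{ptype}_{kind}.csv")
                res.pca[key] = pca
                res.matrices[key] = d_ind
                acoustic[key] = d_ind
                res.tables.setdefault("features", {})[key] = feats
            except Exception as err:
                raise PipelineError(f"stage 'acoustics' [{ptype}/{kind}]: {err}") from err

    # --- genetic side -----------------------------------------------------
    freqs, rm, gdist = _relatedness(cfg, gt)
    rm.matrix.to_csv(out / f"relatedness_{rm.estimator}.csv")
    gdist.to_csv(out / "genetic_distance.csv")
    res.matrices["relatedness"] = rm
    res.matrices["genetic_distance"] = gdist

    if cfg.compare_estimators_n:
        report = compare_estimators(default_loci(), cfg.compare_estimators_n,
                                    np.random.default_rng(
                                        _stage_seed(cfg.seed, "compare")))
        report.to_dataframe().to_csv(out / "estimator_comparison.csv")
        res.tables["estimator_comparison"] = report

    # --- Mantel: population and per sex (Table-1 shape) -------------------
    if cfg.run_mantel:
        rows = []
        for (ptype, kind), d_ind in sorted(acoustic.items()):
            for subgroup in ("males", "females", "overall"):
                if subgroup == "overall":
                    inds = [i for i in d_ind.labels if i in gdist.labels]
                else:
                    want = MALE if subgroup == "males" else FEMALE
                    inds = [i for i in d_ind.labels
                            if i in gdist.labels and sex_of.get(i) == want]
                if len(inds) < 4:
                    log.warning("mantel %s/%s/%s: fewer than 4 individuals; "
                                "skipped", ptype, kind, subgroup)
                    continue
                seed = _stage_seed(cfg.seed, f"mantel:{ptype}:{kind}:{subgroup}")
                try:
                    mr = mantel_test(d_ind.submatrix(inds),
                                     gdist.submatrix(inds),
                                     n_perm=cfg.mantel_permutations,
                                     seed=np.random.default_rng(seed))
                except Exception as err:
                    raise PipelineError(
                        f"stage 'mantel' [{ptype}/{kind}/{subgroup}]: {err}"
                    ) from err
                rows.append((ptype, kind, subgroup, mr.n, mr.r, mr.p))
        t1 = pd.DataFrame(rows, columns=["phrase_type", "parameter_set",
                                         "subgroup", "n", "r", "p"])
        t1.to_csv(out / "table1_mantel.csv", index=False)
        res.tables["mantel"] = t1

    # --- kin-category Mantel (Table-2 shape) -------------------------------
    if cfg.run_kin:
        rows = []
        pairings = ((MALE, MALE), (MALE, FEMALE), (FEMALE, MALE),
                    (FEMALE, FEMALE))
        for (ptype, kind), d_ind in sorted(acoustic.items()):
            for parent_sex, off_sex in pairings:
                design = parent_offspring_design(ped, parent_sex, off_sex,
                                                 present=d_ind.labels)
                name = f"{design.parent_role}-{design.offspring_role}"
                seed = _stage_seed(cfg.seed, f"kin:{ptype}:{kind}:{name}")
                try:
                    mr = kin_category_mantel(d_ind, design,
                                             n_perm=cfg.kin_permutations,
                                             seed=np.random.default_rng(seed))
                    rows.append((ptype, kind, name, mr.n, mr.r, mr.p))
                except ValueError as err:
                    log.warning("kin mantel %s/%s/%s skipped: %s",
                                ptype, kind, name, err)
                    rows.append((ptype, kind, name,
                                 len(design.offspring), np.nan, np.nan))
        t2 = pd.DataFrame(rows, columns=["phrase_type", "parameter_set",
                                         "category", "n_offspring", "r", "p"])
        t2.to_csv(out / "table2_kin_mantel.csv", index=False)
        res.tables["kin_mantel"] = t2

    # --- pDFA (Table-3 shape) ----------------------------------------------
    if cfg.run_pdfa:
        rows = []
        for (ptype, kind), _ in sorted(acoustic.items()):
            scores = res.pca[(ptype, kind)].scores
            meta = res.tables["features"][(ptype, kind)][META_COLUMNS]
            base = PDFAConfig(
                test_factor="individual_id", control_factor="song_id",
                n_selections=cfg.pdfa_selections,
                n_permutations=cfg.pdfa_permutations,
                n_selections_null=cfg.pdfa_selections_null)

            def row(analysis, subgroup, r: "PDFAResult"):
                rows.append((ptype, kind, analysis, subgroup,
                             r.training_rate, r.training_p,
                             r.testing_rate, r.testing_p, r.chance_rate))

            try:
                sd = _stage_seed(cfg.seed, f"pdfa:{ptype}:{kind}:overall")
                row("individuality", "overall",
                    pdfa(scores, meta, dataclasses.replace(
                        base, seed=int(sd.generate_state(1)[0] % 2**31))))
                sd = _stage_seed(cfg.seed, f"pdfa:{ptype}:{kind}:sex")
                by_sex = pdfa_by_sex(scores, meta, dataclasses.replace(
                    base, seed=int(sd.generate_state(1)[0] % 2**31)))
                for sex, r in sorted(by_sex.items()):
                    row("individuality",
                        "males" if sex == MALE else "females", r)
                sd = _stage_seed(cfg.seed, f"pdfa:{ptype}:{kind}:group")
                row("group_membership", "overall",
                    pdfa_group(scores, meta, dataclasses.replace(
                        base, seed=int(sd.generate_state(1)[0] % 2**31))))
            except ValueError as err:
                raise PipelineError(
                    f"stage 'pdfa' [{ptype}/{kind}]: {err}") from err
        t3 = pd.DataFrame(rows, columns=[
            "phrase_type", "parameter_set", "analysis", "subgroup",
            "training_rate", "training_p", "testing_rate", "testing_p",
            "chance_rate"])
        t3.to_csv(out / "table3_pdfa.csv", index=False)
        res.tables["pdfa"] = t3

    # --- manifest ----------------------------------------------------------
    cfg_dict = cfg.to_dict()
    # the manifest describes the analysis, not where it landed on disk
    for run_local in ("out_dir", "log_level"):
        cfg_dict.pop(run_local, None)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "songkin",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
        "library_versions": {"numpy": np.__version__,
                             "pandas": pd.__version__},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    res.manifest = manifest
    return res
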