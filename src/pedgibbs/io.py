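"""CSV readers/writers, run configuration and the end-to-end pipeline.

All tabular I/O is plain CSV with a header.  Output files carry the run
seed and a config hash in a leading ``#`` comment line, which the
package's own readers skip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptive, posterior
from .model import ModelSpec, PosteriorSamples, run_gibbs
from .pedigree import PedigreeTable, validate_and_sort
from .simulate import (
    FACTOR_LEVELS,
    FACTORS,
    SimulationConfig,
    discretize_to_classes,
    quantile_thresholds,
    simulate_dataset,
)

log = logging.getLogger(__name__)


class DataError(ValueError):
    pass


def trait_catalogue() -> pd.DataFrame:
    """Canonical trait abbreviations shipped as package data."""
    with resources.files("pedgibbs.data").joinpath("traits.csv").open() as fh:
        return pd.read_csv(fh)


def trait_names() -> list[str]:
    return trait_catalogue()["abbreviation"].tolist()


_FACTOR_ALIASES: dict[str, dict[str, int]] = {
    "gender": {"male": 1, "m": 1, "female": 2, "f": 2},
    "birth_period": {"<=2000": 1, "2001-2010": 2, ">2010": 3},
    "stud_criteria": {"functionality": 1, "conformation": 2, "routes": 3, "breeding": 4},
    "age_group": {"young": 1, "adult": 2},
    "appraiser": {},
}


def _canonical_factor(col: pd.Series, factor: str) -> pd.Series:
    aliases = _FACTOR_ALIASES[factor]
    levels = FACTOR_LEVELS[factor]

    def conv(v):
        if pd.isna(v):
            raise DataError(f"missing value in factor column {factor!r}")
        s = str(v).strip().lower()
        if s in aliases:
            return aliases[s]
        try:
            iv = int(float(s))
        except ValueError:
            raise DataError(f"unrecognized level {v!r} for factor {factor!r}") from None
        if not 1 <= iv <= levels:
            raise DataError(f"level {iv} out of range 1..{levels} for factor {factor!r}")
        return iv

    return col.map(conv)


def read_phenotypes(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a phenotype-record CSV.

    Mandatory columns: ``animal`` and the five factors; trait columns use
    the canonical abbreviations (a subset is fine, absences are logged).
    ``column_map`` renames user columns to canonical names first.  Scores
    must be 0/1/2; blanks are missing; a numeric score outside the scale
    raises with its row number.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("animal", *FACTORS):
        if col not in df.columns:
            raise DataError(f"phenotype file missing mandatory column {col!r}")
    out = pd.DataFrame({"animal": df["animal"].astype(str)})
    for f in FACTORS:
        out[f] = _canonical_factor(df[f], f)
    for gait in ("walk", "trot"):
        if gait in df.columns:
            out[gait] = pd.to_numeric(df[gait], errors="coerce")

    canonical = trait_names()
    reserved = {"record_id", "animal", "walk", "trot", *FACTORS}
    extra = [c for c in df.columns if c not in reserved and c not in canonical]
    present = [t for t in canonical if t in df.columns] + extra
    absent = [t for t in canonical if t not in df.columns]
    if absent:
        log.info("trait columns absent from %s: %s", path, ", ".join(absent))
    n_unknown = 0
    for trait in present:
        raw = df[trait]
        num = pd.to_numeric(raw, errors="coerce")
        # non-numeric garbage becomes missing (logged); numeric but out of
        # scale is a hard error naming the row
        bad = num.notna() & ~num.isin([0, 1, 2])
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise DataError(
                f"score {raw.iloc[row]!r} outside 0/1/2 for trait {trait!r} "
                f"in data row {row + 2} of {path}"
            )
        n_unknown += int((num.isna() & raw.notna()).sum())
        out[trait] = num
    if n_unknown:
        log.info("%d unparseable scores set to missing", n_unknown)
    if "record_id" in df.columns:
        out.insert(0, "record_id", df["record_id"])
    else:
        out.insert(0, "record_id", np.arange(len(out)))
    return out


def write_phenotypes(records: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records.to_csv(fh, index=False)


def read_pedigree(path) -> PedigreeTable:
    """Load a pedigree CSV (animal,sire,dam,birth_year,sex) and sort it."""
    df = pd.read_csv(path, comment="#", dtype={"animal": str, "sire": str, "dam": str})
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise DataError(f"pedigree file missing mandatory column {col!r}")
    df["sire"] = df["sire"].fillna("")
    df["dam"] = df["dam"].fillna("")
    return validate_and_sort(df)


def write_pedigree(ped: PedigreeTable, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ped.to_frame().to_csv(fh, index=False)


def samples_to_frame(samples: PosteriorSamples) -> pd.DataFrame:
    """Flatten covariance draws to (iteration, component, trait_i, trait_j, value)."""
    rows = []
    t = len(samples.traits)
    for comp, arr in (
        ("sigma_u", samples.sigma_u),
        ("sigma_pe", samples.sigma_pe),
        ("sigma_e", samples.sigma_e),
    ):
        for i in range(t):
            for j in range(i, t):
                for it, v in enumerate(arr[:, i, j]):
                    rows.append((it, comp, samples.traits[i], samples.traits[j], v))
    return pd.DataFrame(
        rows, columns=["iteration", "component", "trait_i", "trait_j", "value"]
    )


def write_samples(samples: PosteriorSamples, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        samples_to_frame(samples).to_csv(fh, index=False)
    meta = {
        "traits": list(samples.traits),
        "spec": {k: v for k, v in asdict(samples.spec).items()},
        **samples.meta,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))


def read_samples(path) -> PosteriorSamples:
    """Rebuild PosteriorSamples from the flat CSV + metadata sidecar."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    traits = tuple(meta["traits"])
    t = len(traits)
    n_saved = int(df["iteration"].max()) + 1
    arrays = {}
    for comp in ("sigma_u", "sigma_pe", "sigma_e"):
        arr = np.zeros((n_saved, t, t))
        sub = df[df["component"] == comp]
        for (ti, tj), grp in sub.groupby(["trait_i", "trait_j"]):
            i, j = traits.index(ti), traits.index(tj)
            vals = grp.sort_values("iteration")["value"].to_numpy()
            arr[:, i, j] = vals
            arr[:, j, i] = vals
        arrays[comp] = arr
    spec_kwargs = meta.get("spec", {})
    spec = ModelSpec(
        traits=traits,
        fixed_factors=tuple(spec_kwargs.get("fixed_factors", FACTORS)),
        n_iterations=int(spec_kwargs.get("n_iterations", n_saved)),
        burn_in=int(spec_kwargs.get("burn_in", 0)),
        thin=int(spec_kwargs.get("thin", 1)),
        seed=int(spec_kwargs.get("seed", 0)),
    )
    return PosteriorSamples(
        traits=traits,
        sigma_u=arrays["sigma_u"],
        sigma_pe=arrays["sigma_pe"],
        sigma_e=arrays["sigma_e"],
        b=None,
        x_names=None,
        spec=spec,
        meta={k: v for k, v in meta.items() if k not in ("traits", "spec")},
    )


def default_discretize(records: pd.DataFrame, traits) -> pd.DataFrame:
    """Map latent simulated scores to 0/1/2 at the 55%/92% quantiles.

    Yields class shares near the more prevalent defects of the study
    design (~55/37/8).  Traits that are already 0/1/2 are left alone.
    """
    thresholds = {}
    for trait in traits:
        vals = records[trait].dropna()
        if set(np.unique(vals)).issubset({0.0, 1.0, 2.0}):
            continue
        thresholds[trait] = quantile_thresholds(vals.to_numpy(), 0.55, 0.37)
    if not thresholds:
        return records
    return discretize_to_classes(records, thresholds, list(thresholds))


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """One pipeline invocation: inputs, toggles and model settings."""

    output_dir: str = "pedgibbs_out"
    phenotypes: str | None = None
    pedigree: str | None = None
    simulate: bool = False
    descriptive: bool = True
    glz: bool = False
    gait: bool = False
    genetic: bool = False
    traits: tuple[str, ...] = ()
    fixed_factors: tuple[str, ...] = FACTORS
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    pe_covariance: str = "identity"
    missing_handling: str = "augment"
    seed: int = 0
    ndigits: int = 2
    mcse_threshold: float = 0.001

    def config_hash(self) -> str:
        # paths excluded: the hash identifies the analysis, not its location
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("output_dir", "phenotypes", "pedigree")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            traits=self.traits,
            fixed_factors=self.fixed_factors,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            missing_handling=self.missing_handling,
            pe_covariance=self.pe_covariance,
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.suffix in (".yml", ".yaml") else json.loads(path.read_text())
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    if "traits" in raw:
        raw["traits"] = tuple(raw["traits"])
    if "fixed_factors" in raw:
        raw["fixed_factors"] = tuple(raw["fixed_factors"])
    return RunConfig(**raw)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages and write every artifact.

    Returns a mapping from artifact name to path.  Convergence warnings
    are soft; structural errors abort with a stage-tagged message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={cfg.seed} config={cfg.config_hash()}"
    artifacts: dict[str, Path] = {}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("load")
        if cfg.simulate:
            sim_cfg = SimulationConfig(seed=cfg.seed, traits=cfg.traits or ("trait1",))
            dataset = simulate_dataset(sim_cfg)
            records, ped = dataset.records, dataset.pedigree
            records = default_discretize(records, sim_cfg.traits)
            write_phenotypes(records, out / "phenotypes.csv", stamp)
            write_pedigree(ped, out / "pedigree.csv", stamp)
            artifacts["phenotypes"] = out / "phenotypes.csv"
            artifacts["pedigree"] = out / "pedigree.csv"
        else:
            if not cfg.phenotypes:
                raise DataError("phenotypes path required when simulate=false")
            records = read_phenotypes(cfg.phenotypes)
            ped = read_pedigree(cfg.pedigree) if cfg.pedigree else None
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    traits = list(cfg.traits) or [
        t for t in trait_names() if t in records.columns
    ] or [c for c in records.columns if c not in ("record_id", "animal", "walk", "trot", *FACTORS)]

    if cfg.descriptive:
        try:
            _stage("descriptive")
            prev = descriptive.prevalence_table(records, traits, ndigits=cfg.ndigits)
            p = out / "prevalence.csv"
            with p.open("w") as fh:
                fh.write(f"# {stamp}\n")
                prev.to_csv(fh, index=False)
            artifacts["prevalence"] = p
        except Exception as exc:
            raise RuntimeError(f"[descriptive] {exc}") from exc

    if cfg.glz:
        try:
            _stage("glz")
            frames = []
            for trait in traits:
                res = descriptive.fit_multinomial_logit(records, trait, cfg.fixed_factors)
                res.insert(0, "trait", trait)
                frames.append(res)
            p = out / "glz_pvalues.csv"
            with p.open("w") as fh:
                fh.write(f"# {stamp}\n")
                pd.concat(frames).to_csv(fh, index=False)
            artifacts["glz"] = p
        except Exception as exc:
            raise RuntimeError(f"[glz] {exc}") from exc

    if cfg.gait:
        try:
            _stage("gait")
            rows = []
            for trait in traits:
                for gait in ("walk", "trot"):
                    if gait not in records.columns:
                        continue
                    res = descriptive.fit_gait_glm(records, trait, gait)
                    for _, r in res.table.iterrows():
                        rows.append(
                            {
                                "trait": trait,
                                "gait": gait,
                                "class": r["class"],
                                "n": r["n"],
                                "mean": r["mean"],
                                "letters": r["letters"],
                                "f_pvalue": res.f_pvalue,
                            }
                        )
            p = out / "gait_comparison.csv"
            with p.open("w") as fh:
                fh.write(f"# {stamp}\n")
                pd.DataFrame(rows).to_csv(fh, index=False)
            artifacts["gait"] = p
        except Exception as exc:
            raise RuntimeError(f"[gait] {exc}") from exc

    if cfg.genetic:
        try:
            _stage("fit")
            if ped is None:
                raise DataError("pedigree required for the genetic stage")
            spec = cfg.model_spec()
            if not spec.traits:
                spec = cfg.model_spec()
            samples = run_gibbs(records, ped, spec)
            write_samples(samples, out / "posterior_draws.csv", stamp)
            artifacts["draws"] = out / "posterior_draws.csv"
            _stage("report")
            report = posterior.summarize_run(
                samples, mcse_threshold=cfg.mcse_threshold, ndigits=cfg.ndigits
            )
            for name, frame in (
                ("heritability", report.heritability),
                ("components", report.components),
                ("correlations", report.correlations),
                ("diagnostics", report.diagnostics),
            ):
                p = out / f"report_{name}.csv"
                with p.open("w") as fh:
                    fh.write(f"# {stamp}\n")
                    frame.to_csv(fh, index=False)
                artifacts[name] = p
            (out / "report.txt").write_text(report.to_text() + "\n")
            artifacts["report_text"] = out / "report.txt"
        except Exception as exc:
            raise RuntimeError(f"[genetic] {exc}") from exc

    run_log = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
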