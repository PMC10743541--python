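"""End-to-end analysis pipeline: simulate/read -> score -> associate -> report.

Driven by a YAML configuration::

    seed: 1
    output_dir: out
    cohort:
      simulate: {n_subjects: 4000}     # overrides onto the default config
      # or:  path: cohort.tsv          # read an existing cohort TSV
    scores: [CERT1, CERT2]
    associations:
      predictors: [cert1, cert2]       # default: the requested score totals
      outcomes: [prevalent, new_onset]
      models: [unadjusted, M1, M2, M3]
    curves:
      - {predictor: cer_18_0, outcome: prevalent, span: 0.75}
    table1:
      grouping: prevalent_status

Every stage writes TSV outputs into ``output_dir`` and the run ends with a
JSON manifest (config hash, seed, package version, exclusion counts, and a
SHA-256 per output file).  Any stage failure aborts the run, removes partial
outputs and raises :class:`~certscore.errors.PipelineError` naming the stage.
Identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, curves, io as cohort_io, models, report, scoring, sim
from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)

_TSV_FLOAT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_TSV_FLOAT)


def run_pipeline(config_path, output_dir=None, seed=None) -> dict:
    """Run the configured pipeline; returns the manifest dict."""
    config_path = Path(config_path)
    raw = config_path.read_text()
    cfg = yaml.safe_load(raw) or {}
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)

    out_dir = Path(cfg.get("output_dir", "certscore_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    run_seed = int(cfg.get("seed", 0))
    created: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        created.append(path)
        return path

    exclusions: dict[str, int] = {}
    stage = "configure"
    try:
        # ---------------- cohort ----------------
        stage = "cohort"
        ccfg = cfg.get("cohort", {"simulate": {}})
        if "path" in ccfg:
            cohort = cohort_io.read_cohort(
                ccfg["path"], ccfg.get("column_map"), ccfg.get("on_bad_row", "error")
            )
            exclusions["cohort_rows_skipped"] = int(cohort.attrs.get("n_skipped", 0))
        elif "simulate" in ccfg:
            overrides = dict(ccfg.get("simulate") or {})
            overrides.setdefault("seed", run_seed)
            base = sim.default_finrisk_config().to_dict()
            base.update(overrides)
            cohort = sim.simulate_cohort(sim.SimulationConfig.from_dict(base))
        else:
            raise ConfigurationError("cohort section needs 'simulate' or 'path'")
        emit("cohort.tsv", lambda p: cohort_io.write_cohort(cohort, p))

        # ---------------- scores ----------------
        stage = "scores"
        score_names = [s.upper() for s in cfg.get("scores", ["CERT1", "CERT2"])]
        work = cohort.copy()
        for name in score_names:
            scores, bounds = scoring.score_cohort(cohort, name)
            exclusions[f"{name.lower()}_missing_lipids"] = scores.attrs["n_excluded"]
            work[name.lower()] = scores["total"].reindex(work.index)
            emit(f"scores_{name}.tsv", lambda p, s=scores: _write_tsv(s, p))
            bdf = pd.DataFrame(
                [
                    {
                        "component": b.component_name,
                        "q25": b.cuts[0], "q50": b.cuts[1], "q75": b.cuts[2],
                        "source": b.source, "degenerate": b.degenerate,
                    }
                    for b in bounds.values()
                ]
            )
            emit(f"boundaries_{name}.tsv", lambda p, b=bdf: _write_tsv(b, p))

        # ---------------- associations ----------------
        stage = "associations"
        acfg = cfg.get("associations", {})
        if acfg is not None:
            predictors = acfg.get("predictors", [s.lower() for s in score_names])
            results = models.run_association_suite(
                work,
                predictors=predictors,
                outcomes=tuple(acfg.get("outcomes", ("prevalent", "new_onset"))),
                models=tuple(acfg.get("models", ("unadjusted", "M1", "M2", "M3"))),
                sex_stratified=bool(acfg.get("sex_stratified", False)),
            )
            emit("associations.tsv", lambda p: _write_tsv(results, p))
            if any(p in models.SCORE_PREDICTORS for p in predictors):
                wide = report.format_cert_table(results)
                emit("associations_cert_wide.tsv", lambda p: _write_tsv(wide, p))

        # ---------------- risk curves ----------------
        stage = "curves"
        for spec in cfg.get("curves", []) or []:
            rc = curves.risk_curve(
                work,
                predictor=spec["predictor"],
                outcome=spec.get("outcome", "prevalent"),
                span=float(spec.get("span", 0.75)),
            )
            emit(
                f"curve_{spec['predictor']}_{spec.get('outcome', 'prevalent')}.tsv",
                lambda p, c=rc: _write_tsv(c.to_frame(), p),
            )

        # ---------------- baseline table ----------------
        stage = "table1"
        tcfg = cfg.get("table1", {})
        if tcfg is not None:
            grouping = tcfg.get("grouping", "prevalent_status")
            table = report.baseline_table(work, grouping)
            emit(f"table1_{grouping}.tsv", lambda p: _write_tsv(table.to_frame(), p))

        # ---------------- manifest ----------------
        stage = "manifest"
        manifest = {
            "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
            "seed": run_seed,
            "version": __version__,
            "n_subjects": int(len(cohort)),
            "exclusions": exclusions,
            "outputs": {p.name: _sha256(p) for p in created},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        logger.info("pipeline complete: %d output file(s) in %s", len(created), out_dir)
        return manifest
    except Exception as exc:
        for p in created:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
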