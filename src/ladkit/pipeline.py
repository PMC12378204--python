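"""Stage orchestration: chain pipeline stages from one RunConfig.

``run_pipeline`` dispatches the stages named in ``cfg.command`` (a ``+``-
separated chain, e.g. ``"synth+quantify+extract"``), wiring each stage's
outputs into the next stage's inputs.  Partial pipelines are allowed; a
stage failure raises with the stage name while earlier artifacts remain on
disk.  If extraction is requested without a cached response surface, a
small surface is built first (logged).
"""

from __future__ import annotations

import logging
from pathlib import Path

from .config import RunConfig, stage_seed, write_manifest

log = logging.getLogger(__name__)

KNOWN_STAGES = ("synth", "quantify", "surface", "extract", "simulate")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception, artifacts: dict):
        self.stage = stage
        self.artifacts = artifacts
        super().__init__(
            f"pipeline stage {stage!r} failed: {err}; completed artifacts: "
            f"{ {k: str(v) for k, v in artifacts.items()} }")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stage chain; returns {artifact name: path}."""
    from click.testing import CliRunner

    from .cli import main

    stages = [s.strip() for s in cfg.command.split("+") if s.strip()]
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    out = Path(cfg.output)
    out.mkdir(parents=True, exist_ok=True)
    import tempfile

    import yaml

    cfg_path = Path(tempfile.mkdtemp()) / "cfg.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg.model_dump(mode="json")))
    runner = CliRunner()
    artifacts: dict = {}

    def invoke(stage, args):
        res = runner.invoke(main, args, catch_exceptions=True)
        if res.exit_code != 0:
            err = res.exception or RuntimeError(res.output.strip())
            raise StageError(stage, err, artifacts)

    for stage in stages:
        sub = out / stage
        base = ["--config", str(cfg_path), "--seed", str(cfg.seed),
                "--out", str(sub)]
        if stage == "synth":
            invoke(stage, ["synth"] + base)
            artifacts["localizations"] = sub / "localizations.csv"
            artifacts["ground_truth"] = sub / "ground_truth.json"
        elif stage == "quantify":
            locs = artifacts.get("localizations") or cfg.input
            if locs is None:
                raise ValueError("quantify needs a synth stage or cfg.input")
            invoke(stage, ["quantify-storm", "--input", str(locs)] + base)
            artifacts["domains"] = sub / "domains.csv"
            artifacts["lad_profile"] = sub / "lad_profile.csv"
        elif stage == "surface":
            invoke(stage, ["surface"] + base)
            artifacts["surface"] = sub / "response_surface.npz"
        elif stage == "extract":
            if "surface" not in artifacts:
                log.info("extract requested without a surface stage; "
                         "building one first")
                invoke("surface", ["surface", "--config", str(cfg_path),
                                   "--seed", str(cfg.seed),
                                   "--out", str(out / "surface")])
                artifacts["surface"] = out / "surface" / \
                    "response_surface.npz"
            invoke(stage, ["extract",
                           "--domains", str(artifacts["domains"]),
                           "--profiles", str(artifacts["lad_profile"]),
                           "--surface", str(artifacts["surface"])] + base)
            artifacts["gamma_me"] = sub / "gamma_me.csv"
            artifacts["v_lad"] = sub / "v_lad.csv"
        elif stage == "simulate":
            invoke(stage, ["simulate"] + base)
            artifacts["sim_domains"] = sub / "domains.csv"
    write_manifest(out, cfg, extra=dict(
        stages=stages, artifacts={k: str(v) for k, v in artifacts.items()}))
    return artifacts
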