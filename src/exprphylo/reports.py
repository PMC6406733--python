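"""Pipeline driver with run provenance.

`run_pipeline` executes the configured stages (discretize -> trees ->
bootstrap -> clades -> enrichment -> screen) on one expression matrix and
writes every artifact plus a JSON manifest recording parameters, input
hashes, seed and tool version.  Deterministic configurations reproduce
their outputs byte-identically; the manifest's content hash excludes the
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path


from . import __version__
from .io_formats import (
    read_expression_table,
    read_gmt,
    read_plate_table,
    write_newick,
)
from .model import ExpressionPhylogeny
from .screen_analysis import (
    density_replicate_correlation,
    fold_change_table,
    plate_position_qc,
    resensitization,
    resistance_calls,
)

__all__ = ["run_pipeline", "RunManifest"]


class StageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage: {stage}] {err}")
        self.stage = stage
        self.original = err


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    def __init__(self, subcommand: str, params: dict, seed=None):
        self.data = {
            "subcommand": subcommand,
            "parameters": params,
            "input_hashes": {},
            "outputs": [],
            "seed": seed,
            "tool_version": __version__,
            "timestamp": None,
        }

    def add_input(self, path) -> None:
        self.data["input_hashes"][str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        # stored relative to the artifact directory so reruns into different
        # directories produce identical manifests
        self.data["outputs"].append(Path(path).name)

    def content_hash(self) -> str:
        body = {k: v for k, v in self.data.items() if k != "timestamp"}
        return hashlib.sha256(
            json.dumps(body, sort_keys=True).encode()
        ).hexdigest()

    def write(self, path) -> None:
        self.data["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.data["content_hash"] = self.content_hash()
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: dict | str, out_dir) -> Path:
    """Run the configured stages; returns the artifact directory.

    Config keys: ``expression`` (path) [+ ``dialect``, ``meta``],
    ``outgroup_rank`` (required), ``methods`` (subset of nj/parsimony/ml),
    ``metric``, ``tau`` ("auto" or a number), ``strategy``, ``bootstrap``
    (replicates, 0 to skip), ``seed``, ``gmt`` (optional path),
    ``screen_ctrl``/``screen_kd`` (optional plate-table paths),
    ``diff_mode``, ``alpha``, ``n_perm``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest = RunManifest("run", config, seed=seed)

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as err:
            raise StageError(name, err) from err

    def emit(path):
        manifest.add_output(path)
        return path

    # ---- load -------------------------------------------------------
    def load():
        if "expression" not in config:
            raise ValueError("config must name an 'expression' matrix")
        manifest.add_input(config["expression"])
        expr = read_expression_table(
            config["expression"],
            dialect=config.get("dialect", "tsv"),
            meta=config.get("meta"),
            log_scale=config.get("log_scale", True),
        )
        if "outgroup_rank" not in config:
            raise ValueError("config must set 'outgroup_rank'")
        return ExpressionPhylogeny(expr, outgroup_rank=config["outgroup_rank"])

    model = stage("load", load)

    methods = config.get("methods", ["nj"])
    results = {}
    for method in methods:
        def fit(method=method):
            return model.fit(
                method=method,
                metric=config.get("metric", "euclidean"),
                tau=config.get("tau", "auto"),
                strategy=config.get("strategy", "nni_from_nj"),
                bootstrap=config.get("bootstrap", 0),
                seed=seed,
            )

        res = stage(f"tree:{method}", fit)
        results[method] = res
        write_newick(res.tree, emit(out / f"tree_{method}.nwk"))
        if res.threshold is not None:
            with open(emit(out / f"threshold_{method}.json"), "w") as fh:
                json.dump(res.threshold.as_dict(), fh, indent=2)
                fh.write("\n")
        with open(emit(out / f"summary_{method}.txt"), "w") as fh:
            fh.write(res.summary() + "\n")

    # ---- clades + enrichment on the first configured method ----------
    primary = results[methods[0]]

    def clades():
        table = primary.differential_genes(
            mode=config.get("diff_mode", "welch_bh"),
            alpha=config.get("alpha", 0.05),
        )
        table.to_csv(emit(out / "differential_genes.tsv"), sep="\t")
        return table

    diff = stage("clades", clades) if config.get("clades", True) else None

    if config.get("gmt"):
        def enrich():
            manifest.add_input(config["gmt"])
            coll = read_gmt(config["gmt"])
            res = primary.enrichment(
                coll, n_perm=config.get("n_perm", 1000), seed=seed
            )
            res.table.to_csv(emit(out / "enrichment.tsv"), sep="\t")
            return res

        stage("enrichment", enrich)

    # ---- screen -------------------------------------------------------
    if config.get("screen_ctrl"):
        def screen():
            manifest.add_input(config["screen_ctrl"])
            ctrl_ds = read_plate_table(config["screen_ctrl"])
            ctrl = fold_change_table(ctrl_ds, arm="ctrl")
            calls = resistance_calls(ctrl, threshold=config.get("resist_threshold", 1.0))
            calls.to_csv(emit(out / "resistance_ctrl.tsv"), sep="\t")
            qc = plate_position_qc(ctrl_ds)
            report = {
                "position_r2": qc.position_r2,
                "n_control_wells": qc.n_control_wells,
                "flags": qc.flags,
                "density_r": density_replicate_correlation(ctrl_ds),
                "n_drugs": calls.attrs["n_drugs"],
                "counts": calls.attrs["counts"],
                "fraction_resistant": calls.attrs["fraction_resistant"],
            }
            if config.get("screen_kd"):
                manifest.add_input(config["screen_kd"])
                kd_ds = read_plate_table(config["screen_kd"])
                kd = fold_change_table(kd_ds, arm="kd")
                rs = resensitization(ctrl, kd, rule=config.get("resens_rule", "below_one"))
                rs.to_csv(emit(out / "resensitization.tsv"), sep="\t")
                report["n_resistant_ctrl"] = rs.attrs["n_resistant_ctrl"]
                report["n_resensitized"] = rs.attrs["n_resensitized"]
                report["fraction_resensitized"] = rs.attrs["fraction_resensitized"]
            with open(emit(out / "screen_report.json"), "w") as fh:
                json.dump(report, fh, indent=2)
                fh.write("\n")

        stage("screen", screen)

    manifest.write(out / "manifest.json")
    return out
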