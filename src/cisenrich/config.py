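"""Strict pipeline configuration: YAML in, validated dataclass out.

Unknown keys are rejected rather than ignored — silent misconfiguration
is the main practical failure mode of enrichment tools. Missing keys take
the published defaults (window 10 kb each side, variance cutoff 0.0025,
correlation cutoff 0.3, p 0.05, confidence 0.95, min term size 5, BH).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .enrich import EnrichConfig
from .errors import ConfigError
from .neighborhood import SearchConfig
from .refine import CoexpressionConfig

_TOP_KEYS = {
    "input", "gtf", "alias_table", "output_dir", "seed", "log_level",
    "neighborhood", "tad", "coexpression", "targets", "biotype",
    "enrichment", "reporting",
}
_NEIGHBOR_KEYS = {
    "upstream_bp", "downstream_bp", "strand_aware", "region_mode",
    "coding_biotypes",
}
_TAD_KEYS = {"path"}
_COEXP_KEYS = {
    "expression", "mode", "method", "variance_cutoff", "coefficient_cutoff",
    "coefficient_rule", "p_cutoff", "confidence_level", "low_expr_value",
    "low_expr_fraction", "log2_transform", "mad_cutoff",
}
_TARGET_KEYS = {"path", "strip_species_prefix"}
_BIOTYPE_KEYS = {"biotypes", "mode"}
_ENRICH_KEYS = {"genesets", "test", "min_set_size", "padj_method", "background"}
_REPORT_KEYS = {"top_n", "rank_by", "graphml"}


@dataclass
class PipelineConfig:
    """Fully validated configuration for one pipeline run."""

    input_path: Path
    gtf_path: Path
    genesets_path: Path
    output_dir: Path
    alias_table: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"
    search: SearchConfig = field(default_factory=SearchConfig)
    tad_path: Optional[Path] = None
    coexpression: Optional[CoexpressionConfig] = None
    expression_path: Optional[Path] = None
    coexpression_mode: str = "filter"
    targets_path: Optional[Path] = None
    strip_species_prefix: bool = False
    biotypes: Optional[frozenset[str]] = None
    biotype_mode: str = "keep"
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    background_path: Optional[Path] = None
    top_n: Optional[int] = None
    rank_by: str = "padj"
    graphml: bool = False


def _check_keys(section: str, raw: dict, allowed: set[str]) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _require(raw: dict, key: str, section: str = "config") -> Any:
    if key not in raw or raw[key] is None:
        raise ConfigError(f"{section}: required key {key!r} is missing")
    return raw[key]


def _as_int(value: Any, key: str, minimum: Optional[int] = None) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ConfigError(f"{key} must be an integer, got {value!r}")
    if minimum is not None and value < minimum:
        raise ConfigError(f"{key} must be >= {minimum}, got {value}")
    return value


def _as_bool(value: Any, key: str) -> bool:
    if not isinstance(value, bool):
        raise ConfigError(f"{key} must be a boolean, got {value!r}")
    return value


def validate_config(raw: dict[str, Any], base_dir: Path | str = ".") -> PipelineConfig:
    """Turn a parsed config mapping into a PipelineConfig, or raise ConfigError."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    base = Path(base_dir)
    _check_keys("config", raw, _TOP_KEYS)

    def _path(v: Any) -> Path:
        p = Path(str(v))
        return p if p.is_absolute() else base / p

    cfg = PipelineConfig(
        input_path=_path(_require(raw, "input")),
        gtf_path=_path(_require(raw, "gtf")),
        genesets_path=_path(
            _require(raw.get("enrichment") or {}, "genesets", "enrichment")
        ),
        output_dir=_path(_require(raw, "output_dir")),
    )
    if raw.get("alias_table"):
        cfg.alias_table = _path(raw["alias_table"])
    if "seed" in raw:
        cfg.seed = _as_int(raw["seed"], "seed", 0)
    if "log_level" in raw:
        level = str(raw["log_level"]).upper()
        if level not in ("DEBUG", "INFO", "WARNING", "WARN", "ERROR"):
            raise ConfigError(f"unknown log_level {raw['log_level']!r}")
        cfg.log_level = "WARNING" if level == "WARN" else level

    nb = raw.get("neighborhood") or {}
    _check_keys("neighborhood", nb, _NEIGHBOR_KEYS)
    try:
        cfg.search = SearchConfig(
            upstream_bp=_as_int(nb.get("upstream_bp", 10_000), "upstream_bp", 0),
            downstream_bp=_as_int(nb.get("downstream_bp", 10_000), "downstream_bp", 0),
            strand_aware=_as_bool(nb.get("strand_aware", False), "strand_aware"),
            region_mode=str(nb.get("region_mode", "gene")),
            coding_biotypes=frozenset(nb.get("coding_biotypes", ["protein_coding"])),
        )
    except Exception as exc:
        raise ConfigError(f"neighborhood: {exc}") from exc

    if raw.get("tad"):
        tad = raw["tad"]
        _check_keys("tad", tad, _TAD_KEYS)
        cfg.tad_path = _path(_require(tad, "path", "tad"))

    if raw.get("coexpression"):
        cx = raw["coexpression"]
        _check_keys("coexpression", cx, _COEXP_KEYS)
        cfg.expression_path = _path(_require(cx, "expression", "coexpression"))
        mode = str(cx.get("mode", "filter"))
        if mode not in ("filter", "expand"):
            raise ConfigError(f"coexpression.mode must be filter|expand, got {mode!r}")
        cfg.coexpression_mode = mode
        try:
            cfg.coexpression = CoexpressionConfig(
                method=str(cx.get("method", "pearson")),
                variance_cutoff=float(cx.get("variance_cutoff", 0.0025)),
                coefficient_cutoff=float(cx.get("coefficient_cutoff", 0.3)),
                coefficient_rule=str(cx.get("coefficient_rule", "absolute")),
                p_cutoff=float(cx.get("p_cutoff", 0.05)),
                confidence_level=float(cx.get("confidence_level", 0.95)),
                low_expr_value=(
                    None if cx.get("low_expr_value") is None
                    else float(cx["low_expr_value"])
                ),
                low_expr_fraction=(
                    None if cx.get("low_expr_fraction") is None
                    else float(cx["low_expr_fraction"])
                ),
                log2_transform=_as_bool(cx.get("log2_transform", False), "log2_transform"),
                mad_cutoff=(
                    None if cx.get("mad_cutoff") is None else float(cx["mad_cutoff"])
                ),
            )
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"coexpression: {exc}") from exc

    if raw.get("targets"):
        tg = raw["targets"]
        _check_keys("targets", tg, _TARGET_KEYS)
        cfg.targets_path = _path(_require(tg, "path", "targets"))
        cfg.strip_species_prefix = _as_bool(
            tg.get("strip_species_prefix", False), "strip_species_prefix"
        )

    if raw.get("biotype"):
        bt = raw["biotype"]
        _check_keys("biotype", bt, _BIOTYPE_KEYS)
        biotypes = _require(bt, "biotypes", "biotype")
        if isinstance(biotypes, str):
            biotypes = [biotypes]
        cfg.biotypes = frozenset(str(b) for b in biotypes)
        mode = str(bt.get("mode", "keep"))
        if mode not in ("keep", "exclude"):
            raise ConfigError(f"biotype.mode must be keep|exclude, got {mode!r}")
        cfg.biotype_mode = mode

    en = raw.get("enrichment") or {}
    _check_keys("enrichment", en, _ENRICH_KEYS)
    try:
        cfg.enrich = EnrichConfig(
            test=str(en.get("test", "hypergeometric")),
            min_set_size=_as_int(en.get("min_set_size", 5), "min_set_size", 1),
            padj_method=str(en.get("padj_method", "BH")),
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"enrichment: {exc}") from exc
    if en.get("background"):
        cfg.background_path = _path(en["background"])

    rp = raw.get("reporting") or {}
    _check_keys("reporting", rp, _REPORT_KEYS)
    if rp.get("top_n") is not None:
        cfg.top_n = _as_int(rp["top_n"], "top_n", 1)
    rank_by = str(rp.get("rank_by", "padj"))
    if rank_by not in ("pval", "padj"):
        raise ConfigError(f"reporting.rank_by must be pval|padj, got {rank_by!r}")
    cfg.rank_by = rank_by
    if "graphml" in rp:
        cfg.graphml = _as_bool(rp["graphml"], "graphml")
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path}: configuration file is empty")
    return validate_config(raw, base_dir=path.parent)
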