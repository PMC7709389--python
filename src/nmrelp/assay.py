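"""The deployed Extended Lipid Panel prediction engine.

Five trained PLS models (TC, TG, apoB, and two HDL-C models routed on the
PLS-predicted TG level), the NIH equation for calculated LDL-C, derived
non-HDL-C, and clinical reportable-range censoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .plscore import PlsModel, model_from_json, model_to_json, predict

__all__ = [
    "LDL_EQUATION_CONSTANTS",
    "REPORTABLE_RANGES",
    "TG_ROUTING_THRESHOLD",
    "ModelBundle",
    "ElpResult",
    "route_hdl_model",
    "compute_ldl_c",
    "apply_reportable_range",
    "predict_elp",
    "round_display",
    "bundle_to_json",
    "bundle_from_json",
]

logger = logging.getLogger(__name__)

#: NIH (Sampson) LDL-C equation constants, mg/dL domain.
LDL_EQUATION_CONSTANTS = {
    "tc_div": 0.948,
    "hdl_div": 0.971,
    "tg_div": 8.56,
    "cross_div": 2140.0,
    "tg_sq_div": 16100.0,
    "offset": 9.44,
}

#: Clinical reportable ranges, mg/dL (lower, upper), per measured analyte.
#: LDL-C and non-HDL-C have no published ranges and are reported uncensored.
REPORTABLE_RANGES = {
    "TC": (66.0, 868.0),
    "TG": (35.0, 950.0),
    "HDLC": (14.0, 152.0),
    "APOB": (35.0, 366.0),
}

TG_ROUTING_THRESHOLD = 250.0

#: TG above this triggers a logged caution: the LDL-C equation was derived
#: for lower TG and extrapolates beyond it.
_TG_WARN_LEVEL = 800.0

_BUNDLE_FORMAT_VERSION = 1


def round_display(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (clinical display convention).

    Operates on the shortest decimal representation so values that read as
    exact halves (e.g. 199.95) round up even when their binary form sits a
    hair below the half.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ModelBundle:
    """The five-model ELP set plus the TG routing threshold."""

    tc: PlsModel
    tg: PlsModel
    apob: PlsModel
    hdl_model_1: PlsModel   # TG < threshold
    hdl_model_2: PlsModel   # TG >= threshold
    tg_routing_threshold: float = TG_ROUTING_THRESHOLD
    version: str = "0"

    def __post_init__(self) -> None:
        if self.tg_routing_threshold <= 0:
            raise ValueError("tg_routing_threshold must be > 0")
        shapes = {
            m.x_mean.shape
            for m in (self.tc, self.tg, self.apob, self.hdl_model_1, self.hdl_model_2)
        }
        if len(shapes) != 1:
            raise ValueError("all five models must share one feature grid")

    @property
    def models(self) -> dict[str, PlsModel]:
        return {
            "tc": self.tc,
            "tg": self.tg,
            "apob": self.apob,
            "hdlc1": self.hdl_model_1,
            "hdlc2": self.hdl_model_2,
        }


@dataclass
class ElpResult:
    """The clinical report record: values, censor flags, display strings.

    ``tc``/``tg``/``hdl_c``/``apob`` hold unrounded predictions;
    ``non_hdl_c`` and ``ldl_c`` are ``None`` when suppressed (any input
    analyte censored, or the LDL-C preconditions violated). Display strings
    carry one-decimal values, or ``"<low"``/``">high"`` when censored.
    """

    sample_id: str
    tc: float
    tg: float
    hdl_c: float
    apob: float
    non_hdl_c: float | None
    ldl_c: float | None
    flags: dict[str, str]
    hdl_model_used: int
    display: dict[str, str] = field(default_factory=dict)


def route_hdl_model(predicted_tg: float, bundle: ModelBundle) -> int:
    """Select the HDL-C model from the uncensored PLS-predicted TG level."""
    if not np.isfinite(predicted_tg):
        raise ValueError("predicted TG must be finite")
    return 2 if predicted_tg >= bundle.tg_routing_threshold else 1


def compute_ldl_c(tc: float, tg: float, hdl_c: float) -> float:
    """Calculated LDL-C (mg/dL) by the NIH equation; unrounded.

    LDL-C = TC/0.948 - HDL-C/0.971
            - (TG/8.56 + TG*(TC - HDL-C)/2140 - TG^2/16100) - 9.44
    """
    if not (tc >= hdl_c >= 0.0):
        raise ValueError(f"need TC >= HDL-C >= 0, got TC={tc}, HDL-C={hdl_c}")
    if tg < 0.0:
        raise ValueError(f"need TG >= 0, got {tg}")
    if tg > _TG_WARN_LEVEL:
        logger.warning(
            "TG=%.1f mg/dL exceeds %.0f; the LDL-C equation extrapolates here",
            tg, _TG_WARN_LEVEL,
        )
    k = LDL_EQUATION_CONSTANTS
    non_hdl = tc - hdl_c
    return (
        tc / k["tc_div"]
        - hdl_c / k["hdl_div"]
        - (tg / k["tg_div"] + tg * non_hdl / k["cross_div"] - tg**2 / k["tg_sq_div"])
        - k["offset"]
    )


def apply_reportable_range(value: float, analyte: str) -> tuple[str, str]:
    """Censor a prediction against its reportable range.

    Returns (flag, display) where flag is ``in_range``/``below``/``above``
    and display is the one-decimal value or ``"<low"``/``">high"``.
    Negative predictions are below-range by definition.
    """
    if analyte not in REPORTABLE_RANGES:
        raise ValueError(f"no reportable range defined for analyte {analyte!r}")
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    lo, hi = REPORTABLE_RANGES[analyte]
    if value < lo:
        return "below", f"<{lo:g}"
    if value > hi:
        return "above", f">{hi:g}"
    return "in_range", f"{round_display(value):.1f}"


def predict_elp(bundle: ModelBundle, x) -> ElpResult:
    """Run the full ELP prediction for one feature vector.

    TC, TG and apoB come from their models; HDL-C from the TG-routed model;
    non-HDL-C and LDL-C are derived from unrounded, uncensored values and
    suppressed whenever an input analyte is censored.
    """
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.shape != bundle.tc.x_mean.shape:
        raise ValueError(
            f"feature grid {values.shape} does not match bundle {bundle.tc.x_mean.shape}"
        )
    sample_id = getattr(x, "sample_id", "")
    tc = predict(bundle.tc, values)
    tg = predict(bundle.tg, values)
    apob = predict(bundle.apob, values)
    hdl_model = route_hdl_model(tg, bundle)
    hdl_c = predict(
        bundle.hdl_model_1 if hdl_model == 1 else bundle.hdl_model_2, values
    )
    if abs(tg - bundle.tg_routing_threshold) <= 2.0:
        # routing continuity audit: log how far apart the two models sit
        alt = predict(
            bundle.hdl_model_2 if hdl_model == 1 else bundle.hdl_model_1, values
        )
        logger.info(
            "TG=%.1f near routing threshold: HDL-C models differ by %.2f mg/dL",
            tg, abs(hdl_c - alt),
        )

    flags: dict[str, str] = {}
    display: dict[str, str] = {}
    for name, value in (("tc", tc), ("tg", tg), ("hdl_c", hdl_c), ("apob", apob)):
        flag, disp = apply_reportable_range(value, _RANGE_KEY[name])
        flags[name] = flag
        display[name] = disp

    inputs_ok = all(flags[k] == "in_range" for k in ("tc", "tg", "hdl_c"))
    non_hdl_c = ldl_c = None
    if flags["tc"] == "in_range" and flags["hdl_c"] == "in_range":
        non_hdl_c = tc - hdl_c
    if inputs_ok:
        try:
            ldl_c = compute_ldl_c(tc, tg, hdl_c)
        except ValueError as exc:
            logger.info("%s: LDL-C suppressed: %s", sample_id, exc)
    else:
        logger.info(
            "%s: LDL-C suppressed: input analyte outside reportable range", sample_id
        )
    display["non_hdl_c"] = "" if non_hdl_c is None else f"{round_display(non_hdl_c):.1f}"
    display["ldl_c"] = "" if ldl_c is None else f"{round_display(ldl_c):.1f}"
    return ElpResult(
        sample_id=sample_id,
        tc=tc,
        tg=tg,
        hdl_c=hdl_c,
        apob=apob,
        non_hdl_c=non_hdl_c,
        ldl_c=ldl_c,
        flags=flags,
        hdl_model_used=hdl_model,
        display=display,
    )


_RANGE_KEY = {"tc": "TC", "tg": "TG", "hdl_c": "HDLC", "apob": "APOB"}


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def bundle_to_json(bundle: ModelBundle) -> str:
    return json.dumps(
        {
            "format_version": _BUNDLE_FORMAT_VERSION,
            "version": bundle.version,
            "tg_routing_threshold": bundle.tg_routing_threshold,
            "models": {
                key: json.loads(model_to_json(m)) for key, m in bundle.models.items()
            },
        }
    )


def bundle_from_json(text: str) -> ModelBundle:
    payload = json.loads(text)
    if payload.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ValueError("unsupported bundle format version")
    models = {
        key: model_from_json(json.dumps(raw))
        for key, raw in payload["models"].items()
    }
    return ModelBundle(
        tc=models["tc"],
        tg=models["tg"],
        apob=models["apob"],
        hdl_model_1=models["hdlc1"],
        hdl_model_2=models["hdlc2"],
        tg_routing_threshold=float(payload["tg_routing_threshold"]),
        version=str(payload.get("version", "0")),
    )
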