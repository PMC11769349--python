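"""QC report aggregation and regulatory-threshold evaluation.

Read-based contamination fractions are **not** converted to mass-based
quantities: turning a read fraction into ng DNA per mg RNA would need
library-prep efficiency and length normalisation that sequencing alone does
not provide.  The report therefore shows read fractions, and evaluates the
two regulatory mass limits — 330 ng DNA per mg RNA (inclusive) and
< 10 ng DNA per dose (strict) — only against user-supplied orthogonal
measurements (qPCR, fluorometry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .polya import PolyAEstimate
from .triage import PairCategory, TriageResult, category_fractions

__all__ = ["RegulatoryLimits", "QCReport", "evaluate_compliance", "build_report"]


@dataclass(slots=True)
class RegulatoryLimits:
    """DNA-impurity limits: EMA 330 ng DNA/mg RNA, FDA < 10 ng DNA/dose."""

    ema_ng_dna_per_mg_rna: float = 330.0
    fda_ng_dna_per_dose: float = 10.0

    def __post_init__(self) -> None:
        if self.ema_ng_dna_per_mg_rna <= 0 or self.fda_ng_dna_per_dose <= 0:
            raise ValueError("regulatory limits must be positive")


def evaluate_compliance(
    measured_ng_per_mg: float | None,
    measured_ng_per_dose: float | None,
    limits: RegulatoryLimits | None = None,
) -> dict[str, dict]:
    """Pass/fail the two DNA-impurity limits against supplied measurements.

    The EMA comparison is inclusive (a measurement equal to the 330 ng/mg
    limit passes); the FDA limit is "less than 10 ng/dose", so a measurement
    of exactly 10 fails.  Missing measurements yield ``not_evaluated``.
    """
    limits = limits or RegulatoryLimits()
    for v in (measured_ng_per_mg, measured_ng_per_dose):
        if v is not None and v < 0:
            raise ValueError("measured DNA quantities must be non-negative")

    def entry(value, threshold, unit, passed):
        return {
            "value": value,
            "threshold": threshold,
            "unit": unit,
            "status": "not_evaluated" if value is None else ("pass" if passed else "fail"),
        }

    return {
        "ema_dna_per_rna": entry(
            measured_ng_per_mg,
            limits.ema_ng_dna_per_mg_rna,
            "ng DNA / mg RNA",
            measured_ng_per_mg is not None
            and measured_ng_per_mg <= limits.ema_ng_dna_per_mg_rna,
        ),
        "fda_dna_per_dose": entry(
            measured_ng_per_dose,
            limits.fda_ng_dna_per_dose,
            "ng DNA / dose",
            measured_ng_per_dose is not None
            and measured_ng_per_dose < limits.fda_ng_dna_per_dose,
        ),
    }


@dataclass
class QCReport:
    """Aggregated identity/purity readout for one sample."""

    sample_id: str
    overall_mapping_pct: float
    category_pcts: dict[str, float]
    contamination: dict
    antisense_pct: float
    polya: dict
    compliance: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in [("overall_mapping_pct", self.overall_mapping_pct),
                        ("antisense_pct", self.antisense_pct),
                        *self.category_pcts.items()]:
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} = {v} outside [0, 100]")

    def comparable_payload(self) -> dict:
        """Everything except run metadata; stable across re-renders."""
        return {
            "sample_id": self.sample_id,
            "overall_mapping_pct": self.overall_mapping_pct,
            "category_pcts": self.category_pcts,
            "contamination": self.contamination,
            "antisense_pct": self.antisense_pct,
            "polya": self.polya,
            "compliance": self.compliance,
        }

    def to_dict(self) -> dict:
        d = self.comparable_payload()
        d["metadata"] = self.metadata
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        d = json.loads(text)
        return cls(
            sample_id=d["sample_id"],
            overall_mapping_pct=d["overall_mapping_pct"],
            category_pcts=d["category_pcts"],
            contamination=d["contamination"],
            antisense_pct=d["antisense_pct"],
            polya=d["polya"],
            compliance=d["compliance"],
            metadata=d.get("metadata", {}),
        )

    def render_tsv(self) -> str:
        """Human-readable two-column rendering; percentages to 2 decimals."""
        lines = [f"sample_id\t{self.sample_id}"]
        lines.append(f"overall_mapping_pct\t{self.overall_mapping_pct:.2f}")
        for cat, pct in self.category_pcts.items():
            lines.append(f"category_{cat}_pct\t{pct:.2f}")
        for cls, frac in self.contamination["fractions"].items():
            lines.append(f"{cls}_pct\t{100.0 * frac:.2f}")
        lines.append(f"antisense_pct\t{self.antisense_pct:.4f}")
        p = self.polya
        lines.append(f"polya_n_support\t{p['n_support']}")
        lines.append(f"polya_n_lower_bound\t{p['n_lower_bound']}")
        for key in ("median", "min", "max", "iqr"):
            v = p[key]
            lines.append(f"polya_{key}\t{'NA' if v is None else v}")
        for name, ent in self.compliance.items():
            lines.append(
                f"compliance_{name}\t{ent['status']}\t"
                f"value={ent['value']}\tlimit={ent['threshold']} {ent['unit']}"
            )
        lines.append(
            "note\tread-based fractions are not converted to mass; mass limits "
            "are evaluated only against supplied orthogonal measurements"
        )
        return "\n".join(lines) + "\n"


def build_report(
    triage: TriageResult,
    polya: PolyAEstimate | None,
    limits: RegulatoryLimits | None = None,
    sample_id: str = "sample",
    measured_ng_per_mg: float | None = None,
    measured_ng_per_dose: float | None = None,
    metadata: dict | None = None,
) -> QCReport:
    """Aggregate triage and poly-A outputs into a :class:`QCReport`."""
    cat_pcts = {
        c.value: p for c, p in category_fractions(triage.category_counts).items()
    }
    polya_dict = (
        polya.to_dict()
        if polya is not None
        else {"n_support": 0, "n_lower_bound": 0, "median": None, "min": None,
              "max": None, "iqr": None}
    )
    return QCReport(
        sample_id=sample_id,
        overall_mapping_pct=triage.overall_mapping_pct,
        category_pcts=cat_pcts,
        contamination={
            "counts": dict(triage.profile.counts),
            "fractions": triage.profile.fractions,
            "total_reads": triage.profile.total_reads,
            "total_pairs": triage.profile.total_pairs,
        },
        antisense_pct=triage.antisense_pct,
        polya=polya_dict,
        compliance=evaluate_compliance(measured_ng_per_mg, measured_ng_per_dose, limits),
        metadata=metadata or {},
    )
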