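"""Model/results objects tying the expression-side stages together.

:class:`HormoneTreatmentModel` holds a validated expression matrix and
four-arm design plus the analysis cut-offs; :meth:`fit` runs the
per-probe statistics, DE calls, Venn/pattern classification and synergy
calls and returns a :class:`HormoneTreatmentResults` carrying every
per-probe table, the derived counts, and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as _de
from . import patterns as _patterns
from . import synergy as _synergy
from .io import (
    Design,
    ExpressionMatrix,
    HORMONE_TREATMENTS,
    ProbeAnnotation,
    read_expression_table,
)
from .thresholds import Thresholds


class HormoneTreatmentModel:
    """Four-arm hormone-treatment analysis of one expression matrix.

    Parameters
    ----------
    matrix, design
        Validated signal matrix and sample map (see
        :func:`hormsynergy.io.read_expression_table`).
    annotation
        Optional probe-to-gene map enabling gene-level collapsing.
    thresholds
        Analysis cut-offs; defaults are the study's printed values.
    synergy_mode
        ``baseline_corrected`` (default) or ``literal_sum`` additive
        expectation.
    test, test_scale
        Per-probe DE test (``welch``/``student``) and the scale it runs
        on (``log2``/``raw``).

    Examples
    --------
    >>> from hormsynergy import simulate
    >>> m, d, truth = simulate.simulate_expression(
    ...     simulate.ExpressionSimConfig(n_probes=500, rng_seed=7))
    >>> res = HormoneTreatmentModel(m, d).fit()
    >>> sorted(res.section_counts) == sorted("abcdefg") + ["none"]
    True
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: Design,
        annotation: ProbeAnnotation | None = None,
        thresholds: Thresholds = Thresholds(),
        synergy_mode: _synergy.AdditiveMode = "baseline_corrected",
        test: str = "welch",
        test_scale: str = "log2",
    ):
        self.matrix = matrix
        self.design = design
        self.annotation = annotation
        self.thresholds = thresholds
        self.synergy_mode = synergy_mode
        self.test = test
        self.test_scale = test_scale

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        design_path: str | Path,
        annotation_path: str | Path | None = None,
        **kwargs,
    ) -> "HormoneTreatmentModel":
        matrix, design = read_expression_table(expression_path, design_path)
        annotation = (
            ProbeAnnotation.read_tsv(annotation_path) if annotation_path else None
        )
        return cls(matrix, design, annotation=annotation, **kwargs)

    def fit(self) -> "HormoneTreatmentResults":
        stats = _de.treatment_stats(
            self.matrix, self.design, test=self.test, test_scale=self.test_scale
        )
        calls = _de.call_de(stats, self.thresholds)
        assignments = _patterns.assign_patterns(
            self.matrix, self.design, stats, calls, self.thresholds
        )
        syn = _synergy.call_synergy(
            calls, stats, self.thresholds, mode=self.synergy_mode
        )
        collapse = (
            _patterns.collapse_probes(assignments, stats, self.annotation)
            if self.annotation is not None
            else None
        )
        return HormoneTreatmentResults(
            model=self,
            probe_stats=stats,
            de_calls=calls,
            assignments=assignments,
            synergy=syn,
            collapse=collapse,
        )


@dataclass
class HormoneTreatmentResults:
    """Fitted per-probe tables and the counts derived from them."""

    model: HormoneTreatmentModel
    probe_stats: pd.DataFrame
    de_calls: pd.DataFrame
    assignments: pd.DataFrame
    synergy: pd.DataFrame
    collapse: _patterns.CollapseResult | None = None

    @property
    def de_counts(self) -> dict[str, int]:
        return {
            tr: int((self.de_calls[tr] != "ns").sum()) for tr in HORMONE_TREATMENTS
        }

    @property
    def section_counts(self) -> dict[str, int]:
        return _patterns.section_counts(self.assignments)

    @property
    def code_counts(self) -> dict[str, int]:
        return _patterns.code_counts(self.assignments)

    @property
    def synergy_counts(self) -> dict[str, int]:
        s = self.synergy
        synergistic = s["criterion"] != "none"
        return {
            "total": int(synergistic.sum()),
            "induced": int((s["direction"] == "induced").sum()),
            "repressed": int((s["direction"] == "repressed").sum()),
            "combined_only": int((s["criterion"] == "combined_only").sum()),
            "greater_than_additive": int(
                (s["criterion"] == "greater_than_additive").sum()
            ),
            "both_criteria": int((s["criterion"] == "both").sum()),
        }

    @property
    def partition_identities(self) -> dict[str, bool]:
        return _patterns.check_partition_identities(self.de_calls, self.assignments)

    def ranked_synergy(self, direction: str, top_n: int | None = 20) -> pd.DataFrame:
        symbols = (
            self.model.annotation.symbol_of()
            if self.model.annotation is not None
            else None
        )
        return _synergy.ranked_synergy_table(
            self.synergy, self.probe_stats, direction, symbols, top_n
        )

    def summary(self) -> str:
        """Plain-text run summary in the style of a model-fit report."""
        th = self.model.thresholds
        s = self.section_counts
        c = self.code_counts
        sy = self.synergy_counts
        n_probes, _ = self.matrix_shape
        lines = [
            "Hormone treatment analysis (T3 / CORT / T3+CORT vs vehicle)",
            "=" * 63,
            f"probes: {n_probes}   replicates/arm: "
            f"{self.model.design.n_replicates('VEH')}",
            f"cut-offs: FC >= {th.fc_cutoff} (|log2FC| >= "
            f"{np.log2(th.fc_cutoff):.5f}), p < {th.alpha_de}; "
            f"refinement p < {th.alpha_refine}",
            f"synergy mode: {self.model.synergy_mode}, margin: "
            f"{th.sd_multiplier} SD",
            "-" * 63,
            "differentially expressed   T3: {T3}   CORT: {CORT}   "
            "T3+CORT: {T3CORT}".format(**self.de_counts),
            "Venn sections   a:{a} b:{b} c:{c} d:{d} e:{e} f:{f} g:{g}".format(**s),
            "section e codes   E1+E2:{0} E3+E4:{1} E5+E6:{2}".format(
                c["E1"] + c["E2"], c["E3"] + c["E4"], c["E5"] + c["E6"]
            ),
            f"synergistic   total:{sy['total']} induced:{sy['induced']} "
            f"repressed:{sy['repressed']} (combined-only:{sy['combined_only']}, "
            f">additive:{sy['greater_than_additive']}, both:{sy['both_criteria']})",
        ]
        if self.collapse is not None:
            lines.append(
                f"gene collapsing   {len(self.collapse.genes)} genes, "
                f"{self.collapse.n_unannotated} unannotated probes dropped, "
                f"{self.collapse.n_conflicts} cross-section conflicts"
            )
        idents = self.partition_identities
        lines.append(
            "partition identities: "
            + ("all hold" if all(idents.values()) else f"VIOLATED {idents}")
        )
        return "\n".join(lines)

    @property
    def matrix_shape(self) -> tuple[int, int]:
        return self.model.matrix.shape

    def to_directory(self, outdir: str | Path) -> None:
        """Write every per-probe table and the gene sets as TSV."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        merged = pd.concat(
            [
                self.probe_stats,
                self.de_calls.add_prefix("de_"),
            ],
            axis=1,
        )
        merged.rename_axis("probe_id").to_csv(out / "probe_stats.tsv", sep="\t")
        self.assignments.rename_axis("probe_id").to_csv(
            out / "pattern_assignments.tsv", sep="\t"
        )
        syn = self.synergy.copy()
        for tr in HORMONE_TREATMENTS:
            syn[f"fc_{tr}"] = self.probe_stats[f"fc_{tr}"]
        syn.rename_axis("probe_id").to_csv(out / "synergy_calls.tsv", sep="\t")
        for direction in ("induced", "repressed"):
            self.ranked_synergy(direction).rename_axis("probe_id").to_csv(
                out / f"top_synergy_{direction}.tsv", sep="\t"
            )
        if self.collapse is not None:
            sets_dir = out / "gene_sets"
            sets_dir.mkdir(exist_ok=True)
            for label, symbols in sorted(self.collapse.sets.items()):
                (sets_dir / f"{label}.txt").write_text(
                    "\n".join(sorted(symbols)) + "\n"
                )
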