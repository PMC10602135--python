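"""Step transition structure: matrix export and nodal/convergent/divergent classes.

Builds the cohort transition matrix from the simulated annotations,
exports it in chord-diagram (tableviewer) layout to
``results/transitions.tsv``, classifies every step by its distinct
predecessor/successor type counts (threshold 10) into
``results/classification.csv``, and renders a transition heatmap.

Run from the repository root:  python analysis/03_transitions_and_classes.py
"""

from pathlib import Path

from procflow.catalog import StepCatalog
from procflow.io import load_annotations
from procflow.transitions import (
    chord_figure,
    classification_frame,
    export_chord_matrix,
    profile_steps,
    transition_matrix,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    catalog = StepCatalog.load(DATA / "catalog.csv")
    cohort = load_annotations(DATA / "events.csv", DATA / "metadata.csv", catalog)

    matrix = transition_matrix(cohort)
    profiles = profile_steps(cohort, threshold=10)

    export_chord_matrix(matrix, OUT / "transitions.tsv")
    frame = classification_frame(profiles, catalog)
    frame.to_csv(OUT / "classification.csv", index=False)
    chord_figure(matrix, OUT / "transitions_heatmap.svg")

    print(f"wrote {OUT / 'transitions.tsv'} ({matrix.total()} transitions), "
          f"{OUT / 'classification.csv'}, {OUT / 'transitions_heatmap.svg'}")
    for cls in ("nodal", "convergent", "divergent"):
        rows = frame[frame["step_class"] == cls]
        names = ", ".join(rows["step_name"]) if not rows.empty else "(none)"
        print(f"  {cls}: {names}")


if __name__ == "__main__":
    main()
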