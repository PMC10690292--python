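"""Merge a single-cell compartment store and aggregate to well profiles.

Image-analysis software emits one relational table per cellular compartment
(cells, cytoplasm, nuclei) keyed by image and object number, with the
cytoplasm table carrying parent links to its cell and nucleus.  The merge
follows those links (object numbers are NOT assumed to agree between
compartments), excludes orphan objects, and the result is aggregated to
one median profile per well.
"""

import tempfile
from pathlib import Path

from morphoscreen import (
    AggregationSpec,
    ScreenDesign,
    aggregate,
    generate_compartment_store,
    load_single_cells,
)

design = ScreenDesign(
    n_plates=1, plate_rows=4, plate_cols=6,
    classes=("Kinase",), treatments_per_class=4,
    cells_per_well=30, orphan_fraction=0.1, seed=1,
)

with tempfile.TemporaryDirectory() as tmp:
    store, truth = generate_compartment_store(design, Path(tmp) / "cells.sqlite")
    cells, report = load_single_cells(store)
    print(f"merged {report.n_cells} cells; orphans excluded per compartment: {report.orphans}")
    print(f"cell table: {len(cells.feature_columns)} compartment-prefixed features")

    wells = aggregate(cells, AggregationSpec(["Metadata_Plate", "Metadata_Well"], "median"))
    print(f"aggregated to {len(wells)} well profiles; "
          f"per-well cell counts sum to {wells.data['Metadata_Object_Count'].sum()}")

# The orphan count reflects the 10% of cells the generator deliberately
# withheld from the cells/cytoplasm tables; merged + orphaned = all objects.
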