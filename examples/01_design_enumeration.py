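"""Enumerate the selection-phase and common-garden designs.

The selection phase crosses 5 salinities (0-4 g/l NaCl) with 4 species
treatments (each ciliate alone, or the three-species community), replicated
3 times. The common garden re-exposes every surviving selection line (minus
T. thermophila) to the gradient, twice per line, with non-zero lines barred
from the zero-salinity garden.
"""

import plastevol as pe

selection = pe.enumerate_selection_design()
cg = pe.enumerate_common_garden_design(selection)

combos = {(m.salinity, m.species_treatment) for m in selection}
print(f"selection microcosms:        {len(selection)}")
print(f"treatment combinations:      {len(combos)}")
print(f"common-garden microcosms:    {len(cg)}")

zero = sum(1 for m in cg if m.historical_salinity == 0)
print(f"  from zero-salinity lines:  {zero}  (9 lines x 5 gardens x 2 reps)")
print(f"  from non-zero lines:       {len(cg) - zero}  (36 lines x 4 gardens x 2 reps)")
# The three counts reproduce the experiment's bookkeeping: 60 selection
# tubes over 20 unique treatment combinations, and 378 common gardens.
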