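"""Build the merged four-window SIM method for the built-in sterol library.

A single quadrupole handles ~17 SIM ions without losing cycle rate, but the
sterol vocabulary needs 20 molecular ions plus fragment and FAP ions.  The
scheduler partitions the elution range into RI-bounded windows and fills
each with the molecular ions actually needed there, padding with adjacent
grid ions and dropping the FAP confirmation ion 126.0 first when the budget
binds.
"""

import fapindex as fx

lib = fx.builtin_library()
method = fx.build_time_windows(lib, budget=17)
for i, w in enumerate(method.windows, 1):
    print(f"window {i}: RI {w.start:.0f}-{w.end:.0f}  ({w.ion_count} ions)")
    print("  retention-independent:",
          ", ".join(f"{mz:g}" for mz in sorted(w.retention_independent_ions)))
    for group, ions in sorted(w.retention_dependent_ions.items()):
        print(f"  {group}: {', '.join(f'{mz:g}' for mz in sorted(ions))}")

report = fx.validate_schedule(method, lib)
print(f"\ncoverage: {int(report.compound_rows['mplus_covered'].sum())}/"
      f"{len(report.compound_rows)} compounds have their molecular ion "
      "monitored in the window where they elute")
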