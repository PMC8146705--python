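"""Scheduled-MRM method inspection: the shipped nine-legume panel.

Loads the reference method (27 markers x 3 transitions, 40 s windows),
re-validates every m/z against the mass arithmetic, and reports how many
transitions the scheduler must monitor simultaneously at the busiest point
of the gradient.
"""

from mrmkit import mrm

panel = mrm.load_reference_panel()
print(f"method: {len(panel)} markers, {len(panel.transitions)} transitions")

issues = mrm.validate_method(panel, tolerance=0.1)
print(f"m/z validation issues at +/-0.1: {len(issues)}")
for it in issues:
    print(f"  {it['marker']} {it['field']}: stored {it['stored']}, "
          f"monoisotopic {it['computed']} (published value is an average-mass figure)")

report = mrm.concurrency_report(panel)
print(f"max concurrent transitions: {report['max_concurrent']} "
      f"at {report['at_time_min']:.2f} min")

# enumerate fresh candidates for one marker, as method design would
cands = mrm.candidate_transitions("DKPSQSGPFNLR", precursor_charge=3)
print(f"DKPSQSGPFNLR (3+): {len(cands)} theoretically explainable "
      f"a/b/y transitions above m/z 250")
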