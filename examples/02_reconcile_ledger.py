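"""Reconcile monthly statements of account against captured invoices.

The statement (the supplier's list of issued invoice numbers) is the
completeness reference: numbers with no captured invoice are missing data,
and the missing rate is the completeness caveat quoted with every total.
"""

import tempfile
from pathlib import Path

from farmabu import SynthConfig, generate_farm, read_invoices, read_statements, reconcile

farm = generate_farm(SynthConfig(seed=42))
with tempfile.TemporaryDirectory() as d:
    farm.write(d)
    invoices = read_invoices(Path(d) / "invoices.csv", catalog=farm.catalog)
    statements = read_statements(Path(d) / "statements.csv")

report = reconcile(statements, invoices)
print(f"invoices issued on statements : {report.n_issued}")
print(f"invoices missing              : {report.n_missing}")
print(f"missing rate                  : {report.missing_rate_percent}%")
print(f"missing numbers               : {report.missing_numbers}")

# The generator deliberately dropped ~3% of invoices while keeping their
# numbers on the statements; the reconciler recovers exactly that set.
assert report.missing_numbers == farm.truth["dropped_invoice_numbers"]
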