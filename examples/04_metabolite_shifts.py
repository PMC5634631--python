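"""Predict metabolite level shifts under glutamine limitation (20 -> 2.5
mM/h) with virtual effluxes, and score sign agreement against the packaged
(synthetic) measurement table."""

from pathlib import Path

import engroflux as ef
from engroflux.sampling import SamplerConfig

net = ef.load_engro1()
pred = ef.predict_shifts(
    net, dict(ef.MEASURED_PANEL), ef.ConditionPair(), SamplerConfig(n_samples=5000, seed=1)
)
print(pred.table[["z", "call"]].round(2).to_string())

table = Path(ef.__file__).parent / "data" / "glutamine_shift_measurements_synthetic.tsv"
expt = ef.ExperimentTable.from_tsv(table)
cmp = ef.compare_with_measurements(pred, expt)
print("\nagreement vs measurements:", dict(cmp.attrs))
print("succinate disagrees by design of the underlying physics: steady-state "
      "flux balance cannot see the ATP/ADP regulation of Complex II.")
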