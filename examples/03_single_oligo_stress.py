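"""One oligodendrocyte under sustained attack: the two-threshold response.

A growing cohort of reactivated T cells occupies one site of a single
5x5 block after another, so repair cannot reclaim the damaged sites.  The
block's healthy-site count falls; when the number of fully damaged sites
sigma reaches omega the cell stops myelinating, and at lambda it
undergoes apoptosis, zeroing all 25 sites.
"""

import numpy as np

from mslesion import SimulationConfig, compute_sigma, init_fields
from mslesion.myelin import degrade, repair, update_oligo_status

config = SimulationConfig(omega=10, lambda_=14)
field, grid = init_fields(config)
block_sites = [(9 + c, 1 + r) for r in range(5) for c in range(5)]

print("attacked sites  sigma  healthy  status")
for i in range(len(block_sites)):
    occupied = block_sites[:i + 1]                # the cohort stays engaged
    for _ in range(config.n_myelin_states - 1):   # grind site i to state 1
        degrade(field, occupied)
        repair(field, grid, occupied, config)
    sigma = compute_sigma(field, grid)
    update_oligo_status(grid, sigma, config, field=field)
    healthy = int((field.state[0:5, 0:5] == config.n_myelin_states).sum())
    print(f"{i + 1:14d}  {sigma[0, 0]:5d}  {healthy:7d}  {grid.status_name(0, 0)}")
    if grid.status[0, 0] == 2:
        break

assert np.all(field.state[0:5, 0:5] == 1)
print("\nApoptosis removed all myelin of the block; the transition sequence "
      "myelinating -> nonmyelinating -> apoptotic is one-way.")
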