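"""Desk-scale replication of the robustness finding: the single-group z test
on the X-by-group interaction is miscalibrated when the mediator residual
variance differs between groups of unequal size, while the multi-group LR
test is not.

Population I-M3 has equal paths in both groups (the null is true) but
psi_M = 0.5 in G1 versus 2.0 in G2. With n_G1 = 200 > n_G2 = 100 the smaller
group has the larger variance and the z test over-rejects; flipping the group
sizes makes it under-reject. 400 replications keep this quick (~15 s);
rejection rates carry +/- 1 Monte Carlo SE.
"""

import groupmediate as gm

pop = gm.population_catalog()["I-M3"]
for n1, n2 in ((150, 150), (200, 100), (100, 200)):
    cond = gm.SimulationCondition(
        population=pop, n_g1=n1, n_g2=n2, n_reps=400,
        methods=("za3S", "LRaM"), seed=99,
    )
    summ = gm.run_condition(cond)
    za, lr = summ.row("za3S", "difference"), summ.row("LRaM", "difference")
    print(f"n=({n1},{n2}):  za3S {za['reject_rate']:.3f} "
          f"(+/-{za['mc_se']:.3f})   LRaM {lr['reject_rate']:.3f} "
          f"(+/-{lr['mc_se']:.3f})")

print(
    "\nNominal level is 0.05. The z test inflates at (200,100) and deflates\n"
    "at (100,200); the LR test stays near 0.05 throughout because the\n"
    "multi-group model estimates a separate residual variance per group."
)
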