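"""How non-random was the learner's spread over quads?

If z experiments land in b quads (max 4 per quad) and all capacity-respecting
placements are equally likely, the number of quads hit f follows
P(f) = C(b,f) [x^z](x+...+x^4)^f / [x^z](1+x+...+x^4)^b.  A full campaign that
hit f quads is compared against this null via the upper-tail probability.
"""

from phenolearn import nonrandomness_tail_p, occupancy_pmf

z, b, f_observed = 2697, 2304, 1670

pmf = occupancy_pmf(z, b, capacity=4)
mode_f = int(pmf.f_values[pmf.probs.argmax()])
print(f"{z} experiments over {b} quads: a random process typically hits "
      f"~{mode_f} quads (distribution mode)")

p = nonrandomness_tail_p(z, b, f_observed)
print(f"observed coverage of {f_observed} quads -> tail probability "
      f"P(f >= {f_observed}) = {p:.3e}")
print("far below 0.05: the learner's sampling was highly non-random, "
      "spreading over many more quads than chance")

count_small = occupancy_pmf(8, 4, method="exact")
print("\nexact small instance (z=8, b=4):",
      dict(zip(count_small.f_values.tolist(), count_small.probs.round(4))))
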