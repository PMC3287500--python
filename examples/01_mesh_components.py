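"""Unary numbers and the basic mesh components.

Builds each r-mesh component, evaluates it through one simulated broadcast,
and prints its output bits and processing-unit (PU) count.
"""

from meshalign.components import adder_subtractor, max_switch_nbit, on_off_switch
from meshalign.mesh import enumerate_port_partitions
from meshalign.unary import decode, encode

parts = enumerate_port_partitions()
illegal = [p for p in parts if not p.is_lr_legal]
print(f"port partitions of (N,S,E,W): {len(parts)}  "
      f"(of which {len(illegal)} are illegal on a Linear r-mesh)")

u = encode(3, 8)
print(f"\n1UN encoding of 3 at width 8: {u}  (a prefix of 3+1 ones)")

w = 8
v, pus = max_switch_nbit([encode(3, w), encode(5, w), encode(4, w)], w)
print(f"\nmax switch on (3, 5, 4): {v} = {decode(v)}   [{pus} PUs]")

v, pus = adder_subtractor(encode(3, w), 3, "add", w)
print(f"adder 3 + 3:             {v} = {decode(v)}   [{pus} PUs on a 3-row mesh]")

v, pus = adder_subtractor(encode(2, w), 5, "subtract", w)
print(f"subtractor 2 - 5:        {v} = {decode(v)}  (all-zero underflow marker)")

v, pus = on_off_switch(encode(5, w), 0, w)
print(f"on/off switch, s=0:      {v} = {decode(v)}  (blocked)   [{pus} PUs]")

print("\nEvery component completes in a single broadcasting step: the bus "
      "carries the OR of everything driven onto it, and OR of unary prefixes "
      "is their maximum.")
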