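"""Build the toy motor and inspect its multi-basin contact maps.

The two conformations share every body-internal contact; what
distinguishes them is the exclusive converter-MH contact sets — the
structural fingerprint of the pre- and post-powerstroke poses.
"""

from gomotor import (ToyMotorSpec, exclusive_contacts, interface_contacts,
                     make_toy_motor, native_contacts, shared_contacts)

pre, post, part = make_toy_motor(ToyMotorSpec())

mh, conv = part["MH"], part["converter"]
body = native_contacts(pre, mh, tag="preMH")
pre_cross = interface_contacts(pre, conv, mh, tag="preConvMH")
post_cross = interface_contacts(post, conv, mh, tag="postConvMH")

print(f"beads: {pre.n_beads} ({mh.size} motor head + {conv.size} converter)")
print(f"MH-internal native contacts:        {len(body)}")
print(f"converter-MH contacts, pre pose:    {len(pre_cross)}")
print(f"converter-MH contacts, post pose:   {len(post_cross)}")
print(f"exclusive to the pre pose:          "
      f"{len(exclusive_contacts(pre_cross, post_cross))}")
print(f"exclusive to the post pose:         "
      f"{len(exclusive_contacts(post_cross, pre_cross))}")
print(f"shared between the poses:           "
      f"{len(shared_contacts(pre_cross, post_cross))}")

# The exclusive sets are disjoint and both non-empty: each pose is
# stabilised by its own dock, which is what lets a dual-basin Hamiltonian
# interconvert between them.
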