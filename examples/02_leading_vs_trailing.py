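"""Leading vs trailing head: structural adaptation of the bound motor.

Runs the two single-basin scenarios (pre-powerstroke converter for the
leading head, post-powerstroke converter for the trailing head, identical
sampling) and compares the distributions that report on ADP release.
"""

from gomotor import ScenarioConfig, run_scenario

bundle = run_scenario(ScenarioConfig(scenario="toy_demo", seed=11,
                                     n_sample=400_000))

modes = bundle["converter_rmsd_modes"]
print(f"converter RMSD mode vs pre reference:")
print(f"  leading  (pre basin):  {modes['leading']:.2f} nm")
print(f"  trailing (post basin): {modes['trailing']:.2f} nm")

for head in ("leading", "trailing"):
    s = bundle[head]["summaries"]
    print(f"{head:9s}: d(switch I, switch II) mean = "
          f"{s['d_swI_swII'].samples.mean():.3f} nm,  "
          f"small-subunit RMSD mode = "
          f"{s['small_subunit_rmsd'].modes[0]:.3f} nm")

# The trailing ensemble sits far from the pre-powerstroke reference
# (converter mode ~3 nm vs ~0.4 nm) and its switch I - switch II distance
# widens - the structural signature associated with faster ADP release
# from the trailing head.
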