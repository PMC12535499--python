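"""Converting retention times into mobile-phase composition.

Retention times shift between instruments, columns and batches, but the
mobile-phase composition at which a compound elutes is a property of the
chemistry.  This script converts a few retention times through the
reference 20 -> 80 %A / 13 min program, shows the dead-volume correction,
and inverts the ramp.
"""

from mzlipid import GradientProgram

program = GradientProgram(a_start=20.0, a_end=80.0, ramp_minutes=13.0)
print(f"program: {program.a_start} -> {program.a_end} %A over {program.ramp_minutes} min")
print(f"slope: {program.slope:.3f} %A per minute\n")

print("RT (min)   %A      %B")
for rt in (0.0, 1.5, 3.25, 6.5, 10.0, 13.0, 15.0):
    a, b = program.composition_at(rt)
    note = "  (post-ramp hold)" if rt > program.ramp_minutes else ""
    print(f"{rt:7.2f} {a:7.2f} {b:7.2f}{note}")

# A 0.4-minute dead volume delays the ramp's arrival at the column:
delayed = GradientProgram(t_delay=0.4)
a_plain, _ = program.composition_at(3.0)
a_delayed, _ = delayed.composition_at(3.0)
print(f"\nat RT 3.0 min: {a_plain:.2f} %A without delay, "
      f"{a_delayed:.2f} %A with a 0.4 min dead volume")

# Inverting the ramp answers "when does the program reach 50 %A?"
print(f"the program reaches 50 %A at t = {program.time_at_composition(50.0):.2f} min")
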