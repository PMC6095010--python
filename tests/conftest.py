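import numpy as np
import pytest

from doralisa import problems as pb
from doralisa.representations import DRIVER, LTM, RECIPIENT, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_knowledge():
    """Perfect predicate weights: each role connected only to its defining semantics."""
    return {role: {s: 1.0 for s in sems} for role, sems in pb.ROLE_SEMANTICS.items()}


@pytest.fixture
def containment_pair():
    """Driver contains(house, square) and recipient contains(circle, triangle).

    Role predicates are clean; the paired objects share no features, so any
    filler correspondence must be carried by role structure alone.  Returns
    (net, driver_analog_id, recipient_analog_id, token-name map).
    """
    net = Network(pool_size=1000, inhibition=0.9)
    driver = net.new_analog(DRIVER)
    recipient = net.new_analog(RECIPIENT)
    out_sems = dict.fromkeys(pb.ROLE_SEMANTICS["outside"], 1.0)
    in_sems = dict.fromkeys(pb.ROLE_SEMANTICS["inside"], 1.0)
    names = {}
    house = net.create_object([100, 101, 102, 103], driver.id)
    square = net.create_object([110, 111, 112, 113], driver.id)
    d_out = net.add_po(driver.id, "predicate", out_sems)
    d_in = net.add_po(driver.id, "predicate", in_sems)
    d_p = net.make_proposition([(d_out.id, house.id), (d_in.id, square.id)], driver.id)
    circle = net.create_object([200, 201, 202, 203], recipient.id)
    triangle = net.create_object([210, 211, 212, 213], recipient.id)
    r_out = net.add_po(recipient.id, "predicate", out_sems)
    r_in = net.add_po(recipient.id, "predicate", in_sems)
    r_p = net.make_proposition(
        [(r_out.id, circle.id), (r_in.id, triangle.id)], recipient.id
    )
    names.update(
        house=house.id, square=square.id, outside_d=d_out.id, inside_d=d_in.id,
        circle=circle.id, triangle=triangle.id, outside_r=r_out.id,
        inside_r=r_in.id, p_d=d_p.id, p_r=r_p.id,
    )
    return net, driver.id, recipient.id, names


@pytest.fixture
def small_world(rng):
    return pb.generate_world(n_objects=30, rng=rng)
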