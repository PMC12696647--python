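<fluxml name="reversible_loop">
  <metabolitepools>
    <pool id="A" atoms="1"/>
    <pool id="B" atoms="1"/>
    <pool id="C" atoms="1"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A" cfg="a"/><rproduct id="B" cfg="a"/></reaction>
    <reaction id="v2" bidirectional="true"><reduct id="B" cfg="a"/><rproduct id="C" cfg="a"/></reaction>
    <reaction id="v3"><reduct id="C" cfg="a"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1</net>
    <xch>v2 &lt;= 3</xch>
  </constraints>
  <configuration id="kin">
    <input pool="A">
      <label cfg="1" purity="0.6"/>
      <label cfg="0" purity="0.4"/>
    </input>
    <measurement>
      <group id="gB" spec="B#M(1)" times="0.3 0.6 1.2 2.4 4.8" sd="0.005"/>
      <group id="gC" spec="C#M(1)" times="0.3 0.6 1.2 2.4 4.8" sd="0.005"/>
    </measurement>
  </configuration>
  <configuration id="stat">
    <input pool="A">
      <label cfg="1" purity="0.6"/>
      <label cfg="0" purity="0.4"/>
    </input>
    <measurement>
      <group id="gBs" spec="B#M(1)" times="inf" sd="0.005"/>
      <group id="gCs" spec="C#M(1)" times="inf" sd="0.005"/>
    </measurement>
  </configuration>
</fluxml>
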