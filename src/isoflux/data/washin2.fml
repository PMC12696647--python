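<fluxml name="washin2">
  <metabolitepools>
    <pool id="S" atoms="1"/>
    <pool id="P1" atoms="1"/>
    <pool id="P2" atoms="1"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="S" cfg="a"/><rproduct id="P1" cfg="a"/></reaction>
    <reaction id="v2"><reduct id="P1" cfg="a"/><rproduct id="P2" cfg="a"/></reaction>
    <reaction id="v3"><reduct id="P2" cfg="a"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1</net>
  </constraints>
  <configuration id="kin">
    <input pool="S"><label cfg="1" purity="1.0"/></input>
    <measurement>
      <group id="gP2" spec="P2#M(1)" times="0.5 1 2 4" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
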