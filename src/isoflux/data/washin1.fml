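<fluxml name="washin1">
  <metabolitepools>
    <pool id="S" atoms="1"/>
    <pool id="P" atoms="1"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="S" cfg="a"/><rproduct id="P" cfg="a"/></reaction>
    <reaction id="v2"><reduct id="P" cfg="a"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1</net>
  </constraints>
  <configuration id="kin">
    <input pool="S"><label cfg="1" purity="1.0"/></input>
    <measurement>
      <group id="gP" spec="P#M(1)" times="0.5 1 2 4" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
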