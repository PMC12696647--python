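<fluxml name="stiff_pools">
  <metabolitepools>
    <pool id="A" atoms="1"/>
    <pool id="B" atoms="1"/>
    <pool id="C" atoms="1"/>
    <pool id="D" atoms="1"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A" cfg="a"/><rproduct id="B" cfg="a"/></reaction>
    <reaction id="v2"><reduct id="B" cfg="a"/><rproduct id="C" cfg="a"/></reaction>
    <reaction id="v3"><reduct id="C" cfg="a"/><rproduct id="D" cfg="a"/></reaction>
    <reaction id="v4"><reduct id="D" cfg="a"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1</net>
  </constraints>
  <configuration id="kin">
    <input pool="A"><label cfg="1" purity="1.0"/></input>
    <measurement>
      <group id="gD" spec="D#M(1)" times="0.5 2 10 40 100" sd="0.01"/>
      <group id="gC" spec="C#M(1)" times="0.5 2 10 40 100" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
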