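<fluxml name="cleave_condense">
  <metabolitepools>
    <pool id="A" atoms="3"/>
    <pool id="B" atoms="2"/>
    <pool id="C" atoms="1"/>
    <pool id="D" atoms="3"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1">
      <reduct id="A" cfg="abc"/><rproduct id="B" cfg="ab"/><rproduct id="C" cfg="c"/>
    </reaction>
    <reaction id="v2" bidirectional="true">
      <reduct id="B" cfg="ab"/><reduct id="C" cfg="c"/><rproduct id="D" cfg="abc"/>
    </reaction>
    <reaction id="v3"><reduct id="D" cfg="abc"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1</net>
    <xch>v2 &lt;= 2</xch>
  </constraints>
  <configuration id="stat">
    <input pool="A">
      <label cfg="111" purity="0.3"/>
      <label cfg="100" purity="0.3"/>
      <label cfg="000" purity="0.4"/>
    </input>
    <measurement>
      <group id="gD" spec="D#M(1,3)" times="inf" sd="0.01"/>
      <group id="gB" spec="B#M(1,2)" times="inf" sd="0.01"/>
    </measurement>
  </configuration>
  <configuration id="kin">
    <input pool="A">
      <label cfg="111" purity="0.3"/>
      <label cfg="100" purity="0.3"/>
      <label cfg="000" purity="0.4"/>
    </input>
    <measurement>
      <group id="gDk" spec="D#M(1,3)" times="0.3 0.8 2 5" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
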