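<fluxml name="branch">
  <metabolitepools>
    <pool id="A" atoms="2"/>
    <pool id="B" atoms="2"/>
    <pool id="C" atoms="2"/>
    <pool id="D" atoms="2"/>
    <pool id="E" atoms="2"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A" cfg="ab"/><rproduct id="B" cfg="ab"/></reaction>
    <reaction id="v2"><reduct id="B" cfg="ab"/><rproduct id="C" cfg="ab"/></reaction>
    <reaction id="v3"><reduct id="B" cfg="ab"/><rproduct id="D" cfg="ba"/></reaction>
    <reaction id="v4"><reduct id="C" cfg="ab"/><rproduct id="E" cfg="ab"/></reaction>
    <reaction id="v5"><reduct id="D" cfg="ab"/><rproduct id="E" cfg="ab"/></reaction>
    <reaction id="v6"><reduct id="E" cfg="ab"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 = 1; v2 &gt;= 0.05; v2 &lt;= 0.95</net>
  </constraints>
  <configuration id="kin">
    <input pool="A"><label cfg="10" purity="1.0"/></input>
    <measurement>
      <group id="gE1" spec="E#M(1)" times="0.4 0.8 1.5 2.5 4 6" sd="0.003"/>
      <group id="gE12" spec="E#M(1,2)" times="0.4 0.8 1.5 2.5 4 6" sd="0.003"/>
      <group id="gB1" spec="B#M(1)" times="0.4 0.8 1.5 2.5 4 6" sd="0.003"/>
      <group id="gC1" spec="C#M(1)" times="0.4 0.8 1.5 2.5 4 6" sd="0.003"/>
    </measurement>
  </configuration>
  <configuration id="stat">
    <input pool="A"><label cfg="10" purity="1.0"/></input>
    <measurement>
      <group id="gE1s" spec="E#M(1)" times="inf" sd="0.003"/>
      <group id="gE12s" spec="E#M(1,2)" times="inf" sd="0.003"/>
    </measurement>
  </configuration>
</fluxml>
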